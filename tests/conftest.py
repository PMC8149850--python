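import numpy as np
import pandas as pd
import pytest

from kelpox.series import SensorSeries


def make_series(
    do,
    temp=None,
    start="2018-01-01",
    interval_minutes=10,
    site_id="TST",
    do_valid=None,
    temp_valid=None,
):
    """Build a gapless series from raw arrays, bypassing file I/O."""
    do = np.asarray(do, dtype=float)
    if temp is None:
        temp = np.full_like(do, 12.0)
    ts = pd.date_range(start, periods=len(do),
                       freq=pd.Timedelta(minutes=interval_minutes))
    return SensorSeries(site_id, ts, np.asarray(temp, dtype=float), do,
                        interval_minutes, temp_valid, do_valid)


@pytest.fixture
def series_factory():
    return make_series


def brute_force_events(do, valid, interval_minutes, threshold=2.0,
                       min_duration_h=1.0, max_gap_minutes=30.0):
    """Independent maximal-run scanner used as the detection oracle.

    Pure-Python sample-by-sample scan: collect every maximal run of valid
    below-threshold samples, merge runs separated only by invalid samples
    whose span is within the gap allowance, then keep runs meeting the
    minimum duration. Returns (first_idx, last_idx, n_below, min_do) tuples.
    """
    runs = []
    current = []
    for i in range(len(do)):
        if valid[i] and do[i] <= threshold:
            current.append(i)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)

    merged = []
    for run in runs:
        if merged:
            gap_indices = range(merged[-1][-1] + 1, run[0])
            gap_ok = (len(gap_indices) * interval_minutes <= max_gap_minutes
                      and all(not valid[j] for j in gap_indices))
            if gap_ok:
                merged[-1] = merged[-1] + run
                continue
        merged.append(run)

    out = []
    for run in merged:
        duration_h = len(run) * interval_minutes / 60.0
        if duration_h >= min_duration_h:
            out.append((run[0], run[-1], len(run),
                        min(do[j] for j in run)))
    return out


@pytest.fixture
def event_oracle():
    return brute_force_events
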