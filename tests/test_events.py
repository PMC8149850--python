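"""Hypoxic-event detection, return times, and exposure summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kelpox.errors import EmptyInputError
from kelpox.events import (
    detect_hypoxic_events, monthly_event_proportions, return_times,
    summarize_exposure,
)

from conftest import brute_force_events, make_series


def _events_as_tuples(series, events):
    pos = {t: i for i, t in enumerate(series.timestamps)}
    return [(pos[e.start], pos[e.end], e.n_samples, e.min_do_mgL)
            for e in events]


class TestDetection:
    def test_never_below_threshold_gives_no_events(self):
        s = make_series(np.full(144 * 30, 6.0))
        assert detect_hypoxic_events(s) == []

    def test_six_sample_run_is_one_hour_event(self):
        do = np.full(144, 6.0)
        do[50:56] = 1.5
        evts = detect_hypoxic_events(make_series(do))
        assert len(evts) == 1
        e = evts[0]
        assert e.duration_h == pytest.approx(1.0)
        assert e.min_do_mgL == 1.5
        assert not e.severe

    def test_five_sample_run_is_too_short(self):
        do = np.full(144, 6.0)
        do[50:55] = 1.5
        assert detect_hypoxic_events(make_series(do)) == []

    def test_severe_flag_below_near_anoxia(self):
        do = np.full(144, 6.0)
        do[30:42] = 0.02
        evts = detect_hypoxic_events(make_series(do))
        assert len(evts) == 1
        assert evts[0].duration_h == pytest.approx(2.0)
        assert evts[0].severe

    def test_sample_exactly_at_threshold_counts(self):
        do = np.full(144, 6.0)
        do[10:16] = 2.0
        assert len(detect_hypoxic_events(make_series(do))) == 1
        assert detect_hypoxic_events(make_series(do), strict=True) == []

    def test_short_invalid_dropout_merges_runs(self):
        do = np.full(144, 6.0)
        do[60:66] = 1.0
        do[68:74] = 1.2
        valid = np.ones(144, dtype=bool)
        valid[66:68] = False  # 20-min dropout between below runs
        evts = detect_hypoxic_events(make_series(do, do_valid=valid))
        assert len(evts) == 1
        assert evts[0].n_samples == 12
        assert evts[0].min_do_mgL == 1.0

    def test_long_dropout_splits_runs(self):
        do = np.full(288, 6.0)
        do[60:66] = 1.0
        do[70:76] = 1.2
        valid = np.ones(288, dtype=bool)
        valid[66:70] = False  # 40 min > default 30-min allowance
        evts = detect_hypoxic_events(make_series(do, do_valid=valid))
        assert len(evts) == 2

    def test_valid_above_threshold_sample_always_splits(self):
        do = np.full(288, 6.0)
        do[60:66] = 1.0
        do[66] = 5.0
        do[67:73] = 1.2
        evts = detect_hypoxic_events(make_series(do))
        assert len(evts) == 2

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(200, 2000))
        do = rng.uniform(0, 8, n)
        valid = rng.random(n) > 0.1
        s = make_series(do, do_valid=valid.copy())
        got = _events_as_tuples(s, detect_hypoxic_events(s))
        want = brute_force_events(do, valid, 10)
        assert got == want

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        do = rng.uniform(0, 8, 600)
        s = make_series(do)
        low = detect_hypoxic_events(s, threshold_mgL=2.0, min_duration_h=0.0)
        high_below = do <= 4.0
        assert sum(e.n_samples for e in low) <= int(high_below.sum())
        pos = {t: i for i, t in enumerate(s.timestamps)}
        for e in low:  # every tight-threshold event sits inside a loose run
            assert high_below[pos[e.start]:pos[e.end] + 1].all()


class TestReturnTimes:
    def _ev(self, do_pattern):
        return detect_hypoxic_events(make_series(do_pattern))

    def test_two_events_two_hours_apart(self):
        do = np.full(144, 6.0)
        do[0:6] = 1.0     # ends at sample 5
        do[18:24] = 1.0   # starts at sample 18 -> 13 intervals later
        evts = self._ev(do)
        assert return_times(evts) == pytest.approx([13 / 6])

    def test_single_event_has_no_return_time(self):
        do = np.full(144, 6.0)
        do[0:6] = 1.0
        assert return_times(self._ev(do)) == []

    def test_three_events_gap_sequence(self):
        do = np.full(144 * 5, 6.0)
        do[0:6] = 1.0
        do[150:156] = 1.0
        do[444:450] = 1.0
        rts = return_times(self._ev(do))
        assert rts == pytest.approx([145 / 6, 289 / 6])
        assert len(rts) == 2  # always n_events - 1


class TestSummaries:
    def test_constant_record(self):
        s = make_series(np.full(144, 6.0), temp=np.full(144, 12.0))
        summ = summarize_exposure(s, [])
        assert summ.do_cv == 0.0
        assert summ.mean_abs_rate_mgL_per_h == 0.0
        assert summ.min_do_mgL == 6.0
        assert summ.mean_temp_C == 12.0
        assert not summ.any_hypoxia
        assert summ.mean_duration_h is None and summ.mean_return_time_h is None

    def test_alternating_do_rate_is_six_per_hour(self):
        do = np.tile([2.0, 3.0], 72)
        summ = summarize_exposure(make_series(do), [])
        assert summ.mean_abs_rate_mgL_per_h == pytest.approx(6.0)

    def test_cv_population_convention(self):
        summ = summarize_exposure(make_series([4.0, 6.0]), [], cv_ddof=0)
        assert summ.do_cv == pytest.approx(0.2)

    def test_cv_sample_convention_default(self):
        summ = summarize_exposure(make_series([4.0, 6.0]), [])
        assert summ.do_cv == pytest.approx(np.sqrt(2) / 5)

    def test_rate_excludes_pairs_spanning_gaps(self):
        do = np.array([6.0, 6.0, 0.0, 6.5, 6.5])
        valid = np.array([True, True, False, True, True])
        summ = summarize_exposure(make_series(do, do_valid=valid), [])
        assert summ.mean_abs_rate_mgL_per_h == pytest.approx(0.0)

    def test_no_valid_samples_is_error(self):
        s = make_series([6.0] * 4, do_valid=np.zeros(4, bool),
                        temp_valid=np.zeros(4, bool))
        with pytest.raises(EmptyInputError):
            summarize_exposure(s, [])

    def test_event_means_from_detected_events(self):
        do = np.full(144 * 3, 6.0)
        do[0:6] = 1.0
        do[100:112] = 1.5
        s = make_series(do)
        evts = detect_hypoxic_events(s)
        summ = summarize_exposure(s, evts)
        assert summ.n_events == 2
        assert summ.mean_duration_h == pytest.approx(1.5)
        assert summ.mean_return_time_h == pytest.approx(95 / 6)


class TestMonthlyProportions:
    def _event_at(self, when):
        do = np.full(12, 1.0)
        s = make_series(do, start=when)
        return detect_hypoxic_events(s)[0]

    def test_all_in_one_month(self):
        evts = [self._event_at(f"2018-06-{d:02d}") for d in (1, 5, 9, 13)]
        props = monthly_event_proportions(evts)
        assert props.proportions[5] == 1.0
        assert sum(props.proportions) == pytest.approx(1.0, abs=1e-12)

    def test_split_between_months(self):
        evts = ([self._event_at("2018-06-01"), self._event_at("2018-06-02")]
                + [self._event_at("2018-07-01"), self._event_at("2018-07-02")])
        props = monthly_event_proportions(evts)
        assert props.proportions[5] == 0.5
        assert props.proportions[6] == 0.5

    def test_boundary_event_counted_in_start_month(self):
        evt = self._event_at("2018-06-30 23:30")  # runs into July
        assert evt.end.month == 7
        props = monthly_event_proportions([evt])
        assert props.proportions[5] == 1.0
        assert props.proportions[6] == 0.0

    def test_zero_events_is_error(self):
        with pytest.raises(EmptyInputError):
            monthly_event_proportions([])

    @given(months=st.lists(st.integers(1, 12), min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_proportions_sum_to_one(self, months):
        evts = [self._event_at(f"2018-{m:02d}-03") for m in months]
        props = monthly_event_proportions(evts)
        assert sum(props.proportions) == pytest.approx(1.0, abs=1e-12)
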