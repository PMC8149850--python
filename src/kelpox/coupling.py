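"""Temperature-oxygen coupling diagnostics.

During wind-driven upwelling, cold deep water low in oxygen is transported
into nearshore habitats, so temperature and dissolved oxygen fall together
and their correlation is strongly positive. When oxygen drawdown is instead
driven by respiration (e.g. decaying algal blooms), DO declines while
temperature does not, and the two decouple. Monthly Pearson correlations
between paired T and DO samples, classified against a coupling threshold
(0.7), separate the two regimes; daily means trace the seasonal trajectory
on a T-DO biplot; and an OLS regression of a summary metric on sensor depth
checks whether deployment depth confounds between-site comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .events import ExposureSummary
from .series import SensorSeries, SiteMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "DailyMeans",
    "MonthlyCoupling",
    "DepthRegression",
    "daily_means",
    "monthly_correlations",
    "depth_min_do_regression",
    "correlate_summary_with_depth",
]

COUPLING_THRESHOLD = 0.7


@dataclass(frozen=True)
class DailyMeans:
    site_id: str
    date: pd.Timestamp
    mean_temp_C: float
    mean_do_mgL: float
    n_valid: int


@dataclass(frozen=True)
class MonthlyCoupling:
    site_id: str
    year_month: pd.Period
    r: float
    n: int
    coupled: bool


@dataclass(frozen=True)
class DepthRegression:
    metric: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_stderr: float
    n_sites: int


def daily_means(
    series: SensorSeries, min_daily_samples: int = 72
) -> list[DailyMeans]:
    """Mean T and DO per calendar day over jointly valid samples.

    Days with fewer than ``min_daily_samples`` valid pairs (default 72,
    half a day at 10-min sampling) are omitted.
    """
    mask = series.valid_mask
    if not mask.any():
        return []
    df = pd.DataFrame(
        {
            "date": series.timestamps[mask].normalize(),
            "t": series.temperature_C[mask],
            "do": series.do_mgL[mask],
        }
    )
    g = df.groupby("date").agg(t=("t", "mean"), do=("do", "mean"), n=("do", "size"))
    g = g[g["n"] >= min_daily_samples]
    return [
        DailyMeans(series.site_id, day, float(row.t), float(row.do), int(row.n))
        for day, row in g.iterrows()
    ]


def monthly_correlations(
    series: SensorSeries,
    coupling_threshold: float = COUPLING_THRESHOLD,
    min_pairs: int = 100,
    method: str = "pearson",
) -> list[MonthlyCoupling]:
    """Correlation between paired T and DO samples per calendar month.

    Months with fewer than ``min_pairs`` jointly valid pairs, or with zero
    variance in either variable (correlation undefined), are omitted with a
    log notice. ``method`` is "pearson" (default) or "spearman".
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    mask = series.valid_mask
    if not mask.any():
        return []
    df = pd.DataFrame(
        {
            "ym": series.timestamps[mask].to_period("M"),
            "t": series.temperature_C[mask],
            "do": series.do_mgL[mask],
        }
    )
    out = []
    for ym, grp in df.groupby("ym"):
        n = len(grp)
        if n < min_pairs:
            logger.info("site %s %s: only %d pairs (<%d), month omitted",
                        series.site_id, ym, n, min_pairs)
            continue
        t, d = grp["t"].to_numpy(), grp["do"].to_numpy()
        if np.ptp(t) == 0 or np.ptp(d) == 0:
            logger.info("site %s %s: zero variance, correlation undefined; omitted",
                        series.site_id, ym)
            continue
        if method == "pearson":
            r = float(stats.pearsonr(t, d).statistic)
        else:
            r = float(stats.spearmanr(t, d).statistic)
        out.append(
            MonthlyCoupling(series.site_id, ym, r, n, coupled=r >= coupling_threshold)
        )
    return out


_NUMERIC_METRICS = (
    "mean_temp_C", "max_temp_C", "min_do_mgL", "do_cv",
    "mean_abs_rate_mgL_per_h", "n_events", "mean_duration_h",
    "mean_return_time_h",
)


def correlate_summary_with_depth(
    summaries: list[ExposureSummary],
    sites: list[SiteMetadata],
    metric_name: str,
) -> DepthRegression:
    """OLS of any numeric exposure metric on sensor depth across sites.

    Sites where the metric is undefined (e.g. mean return time with fewer
    than two events) are excluded; at least three contributing sites are
    required. Reports R^2 and the two-sided p-value of the slope t-test.
    """
    if metric_name not in _NUMERIC_METRICS:
        raise ValidationError(
            f"unknown metric {metric_name!r}; choose from {_NUMERIC_METRICS}"
        )
    depth_by_site: dict[str, float] = {}
    for s in sites:
        if s.site_id in depth_by_site:
            raise ValidationError(f"duplicate site_id {s.site_id!r} in metadata")
        depth_by_site[s.site_id] = s.depth_m
    seen = set()
    xs, ys = [], []
    for summ in summaries:
        if summ.site_id in seen:
            raise ValidationError(f"duplicate site_id {summ.site_id!r} in summaries")
        seen.add(summ.site_id)
        if summ.site_id not in depth_by_site:
            raise ValidationError(f"site {summ.site_id!r} missing from metadata")
        y = getattr(summ, metric_name)
        if y is None or not np.isfinite(y):
            continue
        xs.append(depth_by_site[summ.site_id])
        ys.append(float(y))
    if len(xs) < 3:
        raise InsufficientDataError(
            f"depth regression of {metric_name}: only {len(xs)} usable sites (<3)"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        # degenerate: no variation => no relationship
        return DepthRegression(metric_name, 0.0, float(y.mean()), 0.0, 1.0,
                               np.nan, len(xs))
    res = stats.linregress(x, y)
    return DepthRegression(
        metric=metric_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope_stderr=float(res.stderr),
        n_sites=len(xs),
    )


def depth_min_do_regression(
    summaries: list[ExposureSummary], sites: list[SiteMetadata]
) -> DepthRegression:
    """OLS of site minimum DO on sensor depth (the headline depth check)."""
    return correlate_summary_with_depth(summaries, sites, "min_do_mgL")
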