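"""Sensor time-series containers and I/O.

Nearshore oxygen/temperature loggers record paired measurements on a nominal
uniform grid (typically 1, 5, or 10 minutes). This module reads such records
from delimited text, validates them against physical QC limits, snaps small
clock jitter onto the grid, decimates finer records to a common analysis grid
by subsampling, and fills grid gaps with invalid placeholder samples so that
downstream analyses can assume gapless arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, GridError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "QCLimits",
    "ColumnMap",
    "SiteMetadata",
    "SensorSeries",
    "read_sensor_csv",
    "read_site_table",
    "decimate_to_grid",
    "regularize",
    "write_sensor_csv",
]


@dataclass(frozen=True)
class QCLimits:
    """Physical plausibility limits used to flag samples invalid.

    Defaults span every plausible nearshore value: dissolved oxygen
    0-25 mg/L and seawater temperature -5-45 degC. Values outside the
    limits are retained but masked, never dropped.
    """

    do_min: float = 0.0
    do_max: float = 25.0
    temp_min: float = -5.0
    temp_max: float = 45.0


@dataclass(frozen=True)
class ColumnMap:
    """Names of the timestamp, temperature, and oxygen columns in a file."""

    timestamp: str = "timestamp"
    temperature: str = "temperature_C"
    do: str = "do_mgL"


@dataclass(frozen=True)
class SiteMetadata:
    """One deployment site: location, sensor depth, and instrument."""

    site_id: str
    name: str
    latitude: float
    longitude: float
    depth_m: float
    sensor_type: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"site {self.site_id}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"site {self.site_id}: longitude {self.longitude} outside [-180, 180]"
            )
        if not self.depth_m > 0:
            raise ValidationError(f"site {self.site_id}: depth_m must be > 0")


@dataclass
class SensorSeries:
    """One site's paired temperature/oxygen record on a uniform nominal grid.

    Timestamps are timezone-naive local instants, strictly increasing, and
    every consecutive spacing is a positive integer multiple of
    ``interval_minutes`` (a multiple greater than one marks a gap in the
    record; :func:`regularize` fills gaps with invalid placeholders).

    Per-variable validity masks are retained; ``valid_mask`` is the joint
    mask used for paired statistics. Oxygen-only statistics (event
    detection, CV, rate of change, spectra) use ``do_valid`` alone.
    """

    site_id: str
    timestamps: pd.DatetimeIndex
    temperature_C: np.ndarray
    do_mgL: np.ndarray
    interval_minutes: int
    temp_valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    do_valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.do_mgL = np.asarray(self.do_mgL, dtype=float)
        n = len(self.timestamps)
        if self.temp_valid is None:
            self.temp_valid = np.isfinite(self.temperature_C)
        if self.do_valid is None:
            self.do_valid = np.isfinite(self.do_mgL)
        self.temp_valid = np.asarray(self.temp_valid, dtype=bool)
        self.do_valid = np.asarray(self.do_valid, dtype=bool)
        for name in ("temperature_C", "do_mgL", "temp_valid", "do_valid"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"{name} length {len(getattr(self, name))} != {n} timestamps"
                )
        if self.interval_minutes <= 0:
            raise ValidationError("interval_minutes must be positive")
        if n > 1:
            diffs = np.diff(self.timestamps.asi8) / (60 * 1_000_000_000)
            if np.any(diffs <= 0):
                raise GridError(f"site {self.site_id}: timestamps not strictly increasing")
            mult = diffs / self.interval_minutes
            if not np.allclose(mult, np.round(mult), atol=1e-9):
                raise GridError(
                    f"site {self.site_id}: spacings are not multiples of "
                    f"{self.interval_minutes} min"
                )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def valid_mask(self) -> np.ndarray:
        """Joint mask: sample usable only if both variables are valid."""
        return self.temp_valid & self.do_valid

    @property
    def is_gapless(self) -> bool:
        if len(self) < 2:
            return True
        step = pd.Timedelta(minutes=self.interval_minutes)
        return bool((self.timestamps[1:] - self.timestamps[:-1] == step).all())

    def copy(self) -> "SensorSeries":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            temperature_C=self.temperature_C.copy(),
            do_mgL=self.do_mgL.copy(),
            temp_valid=self.temp_valid.copy(),
            do_valid=self.do_valid.copy(),
        )

    @classmethod
    def from_values(
        cls,
        site_id: str,
        timestamps,
        temperature_C,
        do_mgL,
        interval_minutes: int,
        qc: QCLimits = QCLimits(),
    ) -> "SensorSeries":
        """Build a series, deriving validity masks from the QC limits."""
        t = np.asarray(temperature_C, dtype=float)
        d = np.asarray(do_mgL, dtype=float)
        temp_valid = np.isfinite(t) & (t >= qc.temp_min) & (t <= qc.temp_max)
        do_valid = np.isfinite(d) & (d >= qc.do_min) & (d <= qc.do_max)
        return cls(site_id, pd.DatetimeIndex(timestamps), t, d,
                   interval_minutes, temp_valid, do_valid)


def _infer_interval_minutes(ts: pd.DatetimeIndex) -> int:
    diffs = np.diff(ts.asi8) / (60 * 1_000_000_000)
    interval = int(round(float(np.median(diffs))))
    return max(interval, 1)


def read_sensor_csv(
    path,
    site_id: str,
    columns: ColumnMap = ColumnMap(),
    qc: QCLimits = QCLimits(),
    snap_tolerance_minutes: float = 1.0,
) -> SensorSeries:
    """Read one site's record from delimited text onto its native grid.

    Rows with unparseable timestamps are rejected (counted in a log notice);
    duplicate timestamps keep the first occurrence; timestamps within
    ``snap_tolerance_minutes`` of the grid anchored at the first sample are
    snapped onto it, others rejected. Out-of-range or missing measurement
    values are flagged invalid but never dropped, so the grid is preserved.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: no data") from exc
    for col in (columns.timestamp, columns.temperature, columns.do):
        if col not in raw.columns:
            raise FormatError(f"{path}: required column {col!r} missing "
                              f"(found {list(raw.columns)})")
    ts = pd.to_datetime(raw[columns.timestamp], errors="coerce", format="ISO8601")
    bad_ts = int(ts.isna().sum())
    if bad_ts:
        logger.warning("%s: rejected %d rows with unparseable timestamps", path, bad_ts)
    keep = ts.notna()
    ts = pd.DatetimeIndex(ts[keep])
    temp = pd.to_numeric(raw.loc[keep, columns.temperature], errors="coerce").to_numpy()
    do = pd.to_numeric(raw.loc[keep, columns.do], errors="coerce").to_numpy()
    if len(ts) == 0:
        raise EmptyInputError(f"{path}: zero parseable rows")

    order = np.argsort(ts.asi8, kind="stable")
    ts, temp, do = ts[order], temp[order], do[order]
    interval = _infer_interval_minutes(ts) if len(ts) > 1 else 10

    # snap clock jitter onto the grid anchored at the first sample
    offset_min = (ts.asi8 - ts.asi8[0]) / (60 * 1_000_000_000)
    nearest = np.round(offset_min / interval) * interval
    on_grid = np.abs(offset_min - nearest) <= snap_tolerance_minutes
    n_off = int((~on_grid).sum())
    if n_off:
        logger.warning("%s: rejected %d off-grid rows", path, n_off)
    ts = ts[0] + pd.to_timedelta(nearest[on_grid], unit="m")
    temp, do = temp[on_grid], do[on_grid]

    dup = pd.Index(ts).duplicated(keep="first")
    if dup.any():
        logger.warning("%s: dropped %d duplicate timestamps", path, int(dup.sum()))
        ts, temp, do = ts[~dup], temp[~dup], do[~dup]

    return SensorSeries.from_values(site_id, ts, temp, do, interval, qc=qc)


def read_site_table(path) -> list[SiteMetadata]:
    """Read the site-metadata table (one row per deployment site)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: no data") from exc
    required = {"site_id", "name", "latitude", "longitude", "depth_m"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValidationError(f"{path}: duplicate site_id {dups}")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            SiteMetadata(
                site_id=str(row.site_id),
                name=str(row.name),
                latitude=float(row.latitude),
                longitude=float(row.longitude),
                depth_m=float(row.depth_m),
                sensor_type=str(getattr(row, "sensor_type", "")),
            )
        )
    return sites


def decimate_to_grid(series: SensorSeries, target_minutes: int) -> SensorSeries:
    """Subsample a finer record onto a coarser grid (selection, not averaging).

    Keeps exactly the samples whose timestamps fall on the target grid
    anchored at the first sample; validity flags are carried through.
    """
    if target_minutes % series.interval_minutes != 0:
        raise GridError(
            f"target {target_minutes} min is not a multiple of the native "
            f"{series.interval_minutes}-min interval"
        )
    if target_minutes == series.interval_minutes:
        out = series.copy()
        return out
    offset_min = (series.timestamps.asi8 - series.timestamps.asi8[0]) / (60 * 1_000_000_000)
    keep = np.isclose(offset_min % target_minutes, 0.0)
    return SensorSeries(
        series.site_id,
        series.timestamps[keep],
        series.temperature_C[keep],
        series.do_mgL[keep],
        target_minutes,
        series.temp_valid[keep],
        series.do_valid[keep],
    )


def regularize(series: SensorSeries) -> SensorSeries:
    """Fill missing grid timestamps with invalid placeholder samples.

    The output grid is gapless from the first to the last observed
    timestamp. The fraction of inserted samples is reported in a log notice.
    """
    if series.is_gapless:
        return series.copy()
    full = pd.date_range(
        series.timestamps[0], series.timestamps[-1],
        freq=pd.Timedelta(minutes=series.interval_minutes),
    )
    pos = full.get_indexer(series.timestamps)
    if np.any(pos < 0):  # defended by the SensorSeries grid invariant
        raise GridError(f"site {series.site_id}: off-grid timestamp during regularize")
    n = len(full)
    temp = np.full(n, np.nan)
    do = np.full(n, np.nan)
    tv = np.zeros(n, dtype=bool)
    dv = np.zeros(n, dtype=bool)
    temp[pos] = series.temperature_C
    do[pos] = series.do_mgL
    tv[pos] = series.temp_valid
    dv[pos] = series.do_valid
    inserted = n - len(series)
    logger.info(
        "site %s: inserted %d placeholder samples (%.2f%% of grid)",
        series.site_id, inserted, 100.0 * inserted / n,
    )
    return SensorSeries(series.site_id, full, temp, do, series.interval_minutes, tv, dv)


def write_sensor_csv(series: SensorSeries, path) -> None:
    """Write the normalized per-site layout: timestamp, T, DO, valid flag."""
    pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "temperature_C": series.temperature_C,
            "do_mgL": series.do_mgL,
            "valid": series.valid_mask.astype(int),
        }
    ).to_csv(path, index=False)
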