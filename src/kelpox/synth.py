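"""Synthetic multi-site temperature/oxygen records with known ground truth.

The generator emulates the statistical structure of year-long nearshore
sensor records from an eastern-boundary upwelling coast:

* an annual temperature cycle cooling from autumn to a spring minimum
  (upwelling season) and re-warming through summer;
* synoptic red noise — a first-order autoregressive process with a 4-day
  decorrelation time, mid-range of the 2-10 day weather band;
* diurnal and semidiurnal oscillations in both variables;
* month-by-month temperature-oxygen coupling: in upwelling months the DO
  anomaly tracks the temperature anomaly (DO' = alpha_m * T' + eps, alpha_m
  large), while in respiration-dominated months alpha_m = 0 and DO receives
  independent red-noise excursions;
* injected hypoxic excursions: the record is drawn down to a floor through
  half-cosine ramps (1 h each side) around a plateau of chosen duration,
  so the exact sub-threshold span is known analytically and recorded as
  ground truth;
* white observation noise, applied last; DO is clipped at zero.

Everything is deterministic given the scenario seed. A default 18-site
region scenario arranges a north-to-south gradient of hypoxia exposure
(no events in the north, weekly-scale return times mid-region, many severe
short-return-time events in the south) over the real deployment-site
metadata, for end-to-end recovery tests of the analysis pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .errors import ValidationError
from .series import SensorSeries, SiteMetadata, write_sensor_csv

__all__ = [
    "EventSpec",
    "SiteScenario",
    "TruthEvent",
    "SyntheticTruth",
    "generate_site",
    "generate_region",
    "corrupt",
    "default_region_scenarios",
    "default_site_table",
    "load_scenarios",
    "write_region",
]

EPOCH_START = "2017-10-01"
N_DAYS = 365
INTERVAL_MINUTES = 10

# Default month->coupling coefficient: strong coupling through the
# spring/early-summer upwelling season, decoupled otherwise.
_DEFAULT_COUPLING = {m: (0.85 if m in (3, 4, 5, 6, 7) else 0.0) for m in range(1, 13)}


@dataclass(frozen=True)
class EventSpec:
    """One injected hypoxic excursion.

    ``start`` is the beginning of the ramp-down; the record is held at
    ``floor_mgL`` for ``duration_h`` hours between two half-cosine ramps.
    """

    start: str  # ISO-8601 instant
    duration_h: float
    floor_mgL: float

    @property
    def start_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.start)


@dataclass
class SiteScenario:
    """Everything needed to generate one site's year of data."""

    site_id: str
    seed: int = 0
    start: str = EPOCH_START
    n_days: int = N_DAYS
    interval_minutes: int = INTERVAL_MINUTES
    # temperature structure
    base_temp_C: float = 14.0
    seasonal_amp_C: float = 3.0
    temp_min_date: str = "2018-05-15"  # spring upwelling minimum
    synoptic_sd: float = 0.8
    synoptic_decorrelation_days: float = 4.0
    t_diurnal_amp: float = 0.3
    t_semidiurnal_amp: float = 0.15
    # oxygen structure
    base_do_mgL: float = 7.0
    do_diurnal_amp: float = 0.4
    do_semidiurnal_amp: float = 0.2
    coupling_by_month: dict = field(default_factory=lambda: dict(_DEFAULT_COUPLING))
    decouple_months: tuple = (8, 9)
    decoupled_do_sd: float = 0.5
    event_schedule: tuple = ()  # tuple[EventSpec, ...]
    ramp_h: float = 1.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        self.event_schedule = tuple(
            e if isinstance(e, EventSpec) else EventSpec(*e)
            for e in self.event_schedule
        )
        self.coupling_by_month = {int(k): float(v)
                                  for k, v in self.coupling_by_month.items()}
        for m in range(1, 13):
            self.coupling_by_month.setdefault(m, 0.0)
        amp_sum = (self.do_diurnal_amp + self.do_semidiurnal_amp
                   + self.decoupled_do_sd)
        if self.base_do_mgL - amp_sum < 0:
            raise ValidationError(
                f"site {self.site_id}: base DO {self.base_do_mgL} below the "
                f"sum of oscillation amplitudes {amp_sum}"
            )
        end = pd.Timestamp(self.start) + pd.Timedelta(days=self.n_days)
        prev_end = None
        for ev in self.event_schedule:
            if ev.floor_mgL < 0 or ev.floor_mgL >= self.base_do_mgL:
                raise ValidationError(
                    f"site {self.site_id}: event floor {ev.floor_mgL} outside "
                    f"[0, base DO)"
                )
            w0 = ev.start_ts
            w1 = w0 + pd.Timedelta(hours=ev.duration_h + 2 * self.ramp_h)
            if w0 < pd.Timestamp(self.start) or w1 > end:
                raise ValidationError(
                    f"site {self.site_id}: event at {ev.start} outside the record"
                )
            if prev_end is not None and w0 < prev_end:
                raise ValidationError(
                    f"site {self.site_id}: overlapping or unordered events at "
                    f"{ev.start}"
                )
            prev_end = w1


@dataclass(frozen=True)
class TruthEvent:
    """Ground truth for one injected excursion at the 2 mg/L threshold."""

    start: str
    duration_h: float
    floor_mgL: float
    below_start: str
    below_end: str
    below_duration_h: float
    severe: bool


@dataclass
class SyntheticTruth:
    site_id: str
    seed: int
    events: list  # list[TruthEvent]
    coupled_by_month: dict  # month -> designed-coupled flag
    coupling_by_month: dict  # month -> alpha
    band_amplitudes: dict  # band -> {variable -> amplitude}
    clipped: bool = False

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def mean_duration_h(self) -> float | None:
        if not self.events:
            return None
        return float(np.mean([e.below_duration_h for e in self.events]))

    @property
    def return_times_h(self) -> list[float]:
        out = []
        for prev, nxt in zip(self.events, self.events[1:]):
            gap = pd.Timestamp(nxt.below_start) - pd.Timestamp(prev.below_end)
            out.append(gap / pd.Timedelta(hours=1))
        return out

    @property
    def mean_return_time_h(self) -> float | None:
        rts = self.return_times_h
        return float(np.mean(rts)) if rts else None


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * math.sqrt(1 - phi**2), n)
    innov[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], innov)


def _event_envelope(
    ts: pd.DatetimeIndex, scenario: SiteScenario
) -> tuple[np.ndarray, list[TruthEvent]]:
    """Upper envelope forcing DO down during events, plus analytic truth."""
    env = np.full(len(ts), np.inf)
    truth: list[TruthEvent] = []
    a = scenario.base_do_mgL
    ramp = scenario.ramp_h
    threshold = 2.0
    t_h = (ts.asi8 - ts.asi8[0]) / 3.6e12  # hours since record start
    for ev in scenario.event_schedule:
        f = ev.floor_mgL
        w0 = (ev.start_ts - ts[0]) / pd.Timedelta(hours=1)
        tau = t_h - w0  # hours since ramp-down start
        total = 2 * ramp + ev.duration_h
        win = (tau >= 0) & (tau <= total)
        tw = tau[win]
        vals = np.full(tw.shape, f)
        down = tw < ramp
        vals[down] = f + (a - f) * (1 + np.cos(np.pi * tw[down] / ramp)) / 2
        up = tw > ramp + ev.duration_h
        su = (tw[up] - ramp - ev.duration_h) / ramp
        vals[up] = f + (a - f) * (1 - np.cos(np.pi * su)) / 2
        env[win] = np.minimum(env[win], vals)

        if f < threshold <= a:
            # half-cosine ramp crosses the threshold at fraction s* of the ramp
            c = (threshold - f) / (a - f)
            s_star = math.acos(2 * c - 1) / math.pi
            below_dur = ev.duration_h + 2 * (1 - s_star) * ramp
            below_start = ev.start_ts + pd.Timedelta(hours=s_star * ramp)
            below_end = below_start + pd.Timedelta(hours=below_dur)
            truth.append(
                TruthEvent(
                    start=ev.start,
                    duration_h=ev.duration_h,
                    floor_mgL=f,
                    below_start=below_start.isoformat(),
                    below_end=below_end.isoformat(),
                    below_duration_h=below_dur,
                    severe=f < 0.05,
                )
            )
    return env, truth


def generate_site(scenario: SiteScenario) -> tuple[SensorSeries, SyntheticTruth]:
    """Generate one site's record and its ground truth, deterministically."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_days * int(round(1440 / scenario.interval_minutes))
    ts = pd.date_range(
        scenario.start, periods=n,
        freq=pd.Timedelta(minutes=scenario.interval_minutes),
    )
    dt_days = scenario.interval_minutes / 1440.0
    t_days = np.arange(n) * dt_days

    # temperature: seasonal cycle with a spring minimum + red noise + tides
    days_from_min = (ts - pd.Timestamp(scenario.temp_min_date)) / pd.Timedelta(days=1)
    seasonal = (scenario.base_temp_C
                - scenario.seasonal_amp_C * np.cos(2 * np.pi * days_from_min / 365.25))
    phi = math.exp(-dt_days / scenario.synoptic_decorrelation_days)
    synoptic = _ar1(rng, n, scenario.synoptic_sd, phi)
    t_tides = (scenario.t_diurnal_amp * np.sin(2 * np.pi * t_days)
               + scenario.t_semidiurnal_amp * np.sin(4 * np.pi * t_days))
    t_anom = synoptic + t_tides
    temp_clean = seasonal + t_anom

    # oxygen: coupled anomaly + own oscillations + decoupled excursions
    month = ts.month.to_numpy()
    alpha = np.array([scenario.coupling_by_month[m] for m in range(1, 13)])[month - 1]
    do_tides = (scenario.do_diurnal_amp * np.sin(2 * np.pi * t_days)
                + scenario.do_semidiurnal_amp * np.sin(4 * np.pi * t_days))
    do_clean = scenario.base_do_mgL + alpha * t_anom + do_tides
    if scenario.decouple_months and scenario.decoupled_do_sd > 0:
        resp = _ar1(rng, n, scenario.decoupled_do_sd, phi)
        decouple_mask = np.isin(month, scenario.decouple_months)
        do_clean = do_clean + resp * decouple_mask

    env, truth_events = _event_envelope(ts, scenario)
    do_clean = np.minimum(do_clean, env)

    # observation noise, applied last; truth describes the pre-noise record
    temp = temp_clean + rng.normal(0.0, scenario.noise_sd, n)
    do = do_clean + rng.normal(0.0, scenario.noise_sd, n)
    clipped = bool((do < 0).any())
    do = np.clip(do, 0.0, None)

    series = SensorSeries.from_values(
        scenario.site_id, ts, temp, do, scenario.interval_minutes
    )
    truth = SyntheticTruth(
        site_id=scenario.site_id,
        seed=scenario.seed,
        events=truth_events,
        coupled_by_month={m: scenario.coupling_by_month[m] >= 0.7
                          for m in range(1, 13)},
        coupling_by_month=dict(scenario.coupling_by_month),
        band_amplitudes={
            "diurnal": {"temperature": scenario.t_diurnal_amp,
                        "do": scenario.do_diurnal_amp},
            "semidiurnal": {"temperature": scenario.t_semidiurnal_amp,
                            "do": scenario.do_semidiurnal_amp},
        },
        clipped=clipped,
    )
    return series, truth


def generate_region(
    scenarios: list[SiteScenario],
) -> dict[str, tuple[SensorSeries, SyntheticTruth]]:
    """Generate every site of a region scenario (shared epoch)."""
    if not scenarios:
        raise ValidationError("empty scenario list")
    ids = [s.site_id for s in scenarios]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate site_id in region scenario")
    return {s.site_id: generate_site(s) for s in scenarios}


def corrupt(
    series: SensorSeries,
    gaps: list[tuple] = (),
    invalid_values: list[tuple] = (),
    drop: bool = True,
) -> SensorSeries:
    """Damage a series for QC-path testing.

    ``gaps`` lists (start, length_minutes) holes: samples inside are removed
    from the record when ``drop`` (creating grid gaps for
    :func:`kelpox.series.regularize` to fill) or merely flagged invalid.
    ``invalid_values`` lists (timestamp, variable, value) injections that
    overwrite single samples with out-of-range values and clear their flags.
    """
    out = series.copy()
    keep = np.ones(len(out), dtype=bool)
    for start, length_min in gaps:
        start = pd.Timestamp(start)
        stop = start + pd.Timedelta(minutes=float(length_min))
        hole = (out.timestamps >= start) & (out.timestamps < stop)
        if drop:
            keep &= ~hole
        else:
            out.temp_valid[hole] = False
            out.do_valid[hole] = False
    for when, variable, value in invalid_values:
        idx = out.timestamps.get_indexer([pd.Timestamp(when)])
        if idx[0] < 0:
            raise ValidationError(f"injection instant {when} not on the grid")
        if variable == "do":
            out.do_mgL[idx[0]] = value
            out.do_valid[idx[0]] = False
        else:
            out.temperature_C[idx[0]] = value
            out.temp_valid[idx[0]] = False
    if not keep.all():
        out = SensorSeries(
            out.site_id, out.timestamps[keep], out.temperature_C[keep],
            out.do_mgL[keep], out.interval_minutes,
            out.temp_valid[keep], out.do_valid[keep],
        )
    return out


# --- default 18-site region ------------------------------------------------

# Deployment-site metadata for the default region (site, lat, lon, depth m,
# sensor), spanning ~13 degrees of latitude from northern California to
# central Baja California Sur.
_SITE_ROWS = [
    ("1-VD", "Van Damme, CA", 39.271833, -123.79563, 10, "PME MiniDOT"),
    ("2-MRY", "Monterey, CA", 36.621, -121.899, 17,
     "GF Signet Resistance Thermometer, In Situ RDO Pro-X"),
    ("3-SD", "San Diego, CA", 32.81320, -117.29006, 20, "PME MiniDOT"),
    ("4-SPF", "El Rosario, BC", 29.79099, -115.80957, 14, "PME MiniDOT"),
    ("5-PN", "Punta Norte, BC", 28.3532, -115.19258, 9, "PME MiniDOT"),
    ("6-PP", "Punta Prieta, BCS", 27.88691, -115.18875, 14,
     "PME MiniDOT/ Seabird SBE 37"),
    ("7-MP", "Morro Prieto, BCS", 27.87984, -115.21378, 15,
     "PME MiniDOT/ Seabird SBE 37"),
    ("8-EUG", "Punta Eugenia, BCS", 27.83632, -115.07539, 10, "PME MiniDOT"),
    ("9-VIZ", "Bahia Vizcaino, BCS", 27.8105, -114.50412, 10.5, "PME MiniDOT"),
    ("10-CB", "Clam Bay, BCS", 27.62015, -114.84217, 6, "PME MiniDOT"),
    ("11-PER", "Punta Perico, BCS", 27.5271, -114.74084, 13, "PME MiniDOT"),
    ("12-CAS", "Puerto Castro, BCS", 27.17093, -114.42178, 11, "PME MiniDOT"),
    ("13-GAV", "Los Gavilanes, BCS", 27.10345, -114.2965, 9, "PME MiniDOT"),
    ("14-PAT", "Piedra Pato, BCS", 27.00639, -114.04489, 14, "PME MiniDOT"),
    ("15-HIP", "San Hipolito, BCS", 26.987267, -113.97182, 7, "PME MiniDOT"),
    ("16-BCN", "Bocanita, BCS", 26.79495, -113.72841, 10, "PME MiniDOT"),
    ("17-RIN", "Rincon, BCS", 26.77482, -113.69234, 11, "PME MiniDOT"),
    ("18-ABR", "Punta Abreojos, BCS", 26.74856, -113.50941, 12, "PME MiniDOT"),
]


def default_site_table() -> list[SiteMetadata]:
    """Metadata for the 18 default region sites, ordered north to south."""
    return [SiteMetadata(*row) for row in _SITE_ROWS]


def _evenly_spaced_events(
    first_start: pd.Timestamp,
    n_events: int,
    duration_h: float,
    spacing_h: float,
    floor: float,
    ramp_h: float,
) -> tuple:
    """Chronological, non-overlapping schedule with constant spacing."""
    events = []
    t = first_start
    step = pd.Timedelta(hours=duration_h + 2 * ramp_h + spacing_h)
    for _ in range(n_events):
        events.append(EventSpec(t.isoformat(), duration_h, floor))
        t = t + step
    return tuple(events)


def default_region_scenarios(seed: int = 0) -> list[SiteScenario]:
    """18 site scenarios with a designed north-to-south exposure gradient.

    Northern sites (1-6) never go hypoxic. Mid-region sites (7-13) see a
    few events in summer with return times of days to weeks, floors well
    above near-anoxia. The five southern sites (14-18) see many short
    events with sub-daily return times and severe (< 0.05 mg/L) minima.
    Every event-bearing site is distinct in event count, duration, and
    spacing, so exposure orderings are recoverable exactly. Spring months
    (Mar-May) are designed coupled at every site; summer and winter months
    are decoupled, with respiration-style independent DO excursions at the
    event-bearing sites in summer.
    """
    rng = np.random.default_rng(seed)
    coupled = {m: (0.85 if m in (3, 4, 5) else 0.0) for m in range(1, 13)}
    scenarios = []
    for i, (site_id, _, lat, _, _, _) in enumerate(_SITE_ROWS):
        base_temp = 11.0 + 0.55 * (39.3 - lat)  # warmer southward
        common = dict(
            site_id=site_id,
            seed=int(rng.integers(0, 2**31 - 1)),
            base_temp_C=base_temp,
            coupling_by_month=dict(coupled),
        )
        if i < 6:  # north: no hypoxia, quiet summers
            scenarios.append(SiteScenario(
                **common, decouple_months=(6, 7, 8, 9), decoupled_do_sd=0.3,
            ))
        elif i < 13:  # mid: sparse events, return times of days to weeks
            k = i - 6
            scenarios.append(SiteScenario(
                **common,
                decouple_months=(6, 7, 8, 9), decoupled_do_sd=0.4,
                event_schedule=_evenly_spaced_events(
                    pd.Timestamp("2018-06-03") + pd.Timedelta(hours=6 * k),
                    n_events=3 + k,
                    duration_h=1.5 + 0.15 * k,
                    spacing_h=504.0 - 68.0 * k,  # 21 days down to ~4 days
                    floor=1.2,
                    ramp_h=1.0,
                ),
            ))
        else:  # south: many short severe events, sub-daily return times
            k = i - 13
            scenarios.append(SiteScenario(
                **common,
                base_do_mgL=6.5,
                decouple_months=(6, 7, 8, 9), decoupled_do_sd=0.4,
                event_schedule=_evenly_spaced_events(
                    pd.Timestamp("2018-06-01") + pd.Timedelta(hours=3 * k),
                    n_events=40 + 8 * k,
                    duration_h=2.6 + 0.2 * k,
                    spacing_h=20.0 - 3.0 * k,  # 20 h down to 8 h
                    floor=0.04 - 0.005 * k,
                    ramp_h=1.0,
                ),
            ))
    return scenarios


# --- scenario files and dataset output -------------------------------------

def load_scenarios(path) -> list[SiteScenario]:
    """Read a region scenario file (YAML): global defaults + per-site keys."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "sites" not in doc:
        raise ValidationError(f"{path}: scenario file needs a 'sites' list")
    defaults = doc.get("defaults", {})
    scenarios = []
    for entry in doc["sites"]:
        cfg = {**defaults, **entry}
        if "events" in cfg:
            cfg["event_schedule"] = tuple(
                EventSpec(str(e[0]), float(e[1]), float(e[2]))
                for e in cfg.pop("events")
            )
        if "decouple_months" in cfg:
            cfg["decouple_months"] = tuple(int(m) for m in cfg["decouple_months"])
        scenarios.append(SiteScenario(**cfg))
    return scenarios


def write_region(
    region: dict[str, tuple[SensorSeries, SyntheticTruth]],
    out_dir,
    sites: list[SiteMetadata] | None = None,
) -> None:
    """Write a generated region in the standard per-site CSV layout.

    Emits one ``<site_id>.csv`` per site, a ``sites.csv`` metadata table
    (default-region metadata when none is given), and ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_doc = {}
    for site_id, (series, truth) in region.items():
        write_sensor_csv(series, out / f"{site_id}.csv")
        truth_doc[site_id] = {
            "seed": truth.seed,
            "events": [asdict(e) for e in truth.events],
            "coupled_by_month": {str(k): v for k, v in truth.coupled_by_month.items()},
            "coupling_by_month": {str(k): v
                                  for k, v in truth.coupling_by_month.items()},
            "band_amplitudes": truth.band_amplitudes,
            "clipped": truth.clipped,
        }
    if sites is None:
        known = {s.site_id: s for s in default_site_table()}
        sites = [known[sid] for sid in region if sid in known]
    if sites:
        pd.DataFrame([asdict(s) for s in sites]).to_csv(out / "sites.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=1)
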