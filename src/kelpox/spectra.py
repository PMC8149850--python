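"""Band-integrated variance spectra of oxygen and temperature records.

Timescales of nearshore variability are summarised by a Welch spectral
estimate — averaged periodograms over long overlapping Hamming-tapered
segments (default 90 days, 50% overlap) — expressed as a one-sided density
in (units)^2 per cycle-per-day and renormalised so its trapezoidal integral
over frequency equals the variance of the analyzed record. The density is
then integrated over four period bands:

* seasonal:     0.01-0.05 cpd (20-100 day cycles)
* synoptic:     0.1-0.5 cpd  (2-10 day weather / mesoscale variability)
* diurnal:      0.75-1.25 cpd (~24-h day-night and internal-wave cycles)
* semidiurnal:  1.75-2.25 cpd (~12-h tidal cycles)

The band with the largest integrated variance is the record's dominant
timescale. Note that with 90-day segments the frequency resolution is
1/90 ~ 0.011 cpd, so only a handful of frequencies resolve inside the
seasonal band; its integral is reported but is coarse below ~0.02 cpd.

Gap policy: interior gaps up to 6 h are filled by linear interpolation;
segments still containing longer gaps are dropped from the Welch average.
Interpolation across long gaps would bias high-frequency variance downward,
so dropping whole segments is the safer default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig

from .errors import BandResolutionError, ConfigError, UndefinedDominanceError
from .series import SensorSeries, regularize

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumConfig",
    "BandSpectrum",
    "BANDS_CPD",
    "welch_variance_spectrum",
    "integrate_band",
    "dominant_band",
]

# band name -> (low, high) in cycles per day; ordered low to high frequency
BANDS_CPD: dict[str, tuple[float, float]] = {
    "seasonal": (0.01, 0.05),
    "synoptic": (0.1, 0.5),
    "diurnal": (0.75, 1.25),
    "semidiurnal": (1.75, 2.25),
}

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class SpectrumConfig:
    segment_days: float = 90.0
    overlap_fraction: float = 0.5
    window_shape: str = "hamming"
    detrend: str = "mean"  # "mean" | "linear"
    max_gap_fill_h: float = 6.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ConfigError("overlap_fraction must be in [0, 1)")
        if self.segment_days <= 0:
            raise ConfigError("segment_days must be positive")
        if self.detrend not in ("mean", "linear"):
            raise ConfigError(f"unknown detrend {self.detrend!r}")


@dataclass
class BandSpectrum:
    site_id: str
    variable: str  # "do" | "temperature"
    frequencies_cpd: np.ndarray
    psd: np.ndarray  # (variable units)^2 per cpd, one-sided
    band_variance: dict = field(default_factory=dict)
    total_variance: float = 0.0
    dominant: str | None = None
    n_segments: int = 0


def _fill_short_gaps(x: np.ndarray, valid: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior invalid runs of length <= max_gap."""
    out = x.astype(float).copy()
    out[~valid] = np.nan
    if valid.all() or not valid.any():
        return out
    idx = np.arange(len(x))
    bad = ~valid
    padded = np.concatenate(([False], bad, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for a, b in zip(edges[::2], edges[1::2]):
        if a == 0 or b == len(x):
            continue  # leading/trailing gaps are not interior
        if b - a <= max_gap:
            out[a:b] = np.interp(idx[a:b], [a - 1, b], [out[a - 1], out[b]])
    return out


def _detrend(seg: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean":
        return seg - seg.mean()
    t = np.arange(len(seg), dtype=float)
    slope, intercept = np.polyfit(t, seg, 1)
    return seg - (slope * t + intercept)


def welch_variance_spectrum(
    series: SensorSeries,
    variable: str = "do",
    config: SpectrumConfig = SpectrumConfig(),
) -> BandSpectrum:
    """Variance-scaled Welch spectrum of one variable of a site record.

    Returns a one-sided density on a cycles-per-day frequency axis whose
    trapezoidal integral equals the variance of the (gap-filled) record,
    with the four band integrals and the dominant band attached.
    """
    if variable not in ("do", "temperature"):
        raise ConfigError(f"variable must be 'do' or 'temperature', got {variable!r}")
    s = regularize(series)
    if variable == "do":
        x, valid = s.do_mgL, s.do_valid
    else:
        x, valid = s.temperature_C, s.temp_valid

    samples_per_day = MINUTES_PER_DAY / s.interval_minutes
    fs_cpd = samples_per_day  # sampling frequency in cycles per day
    nperseg = int(round(config.segment_days * samples_per_day))
    if nperseg < 2 or nperseg > len(s):
        raise ConfigError(
            f"record of {len(s)} samples is shorter than one "
            f"{config.segment_days}-day segment ({nperseg} samples); "
            "reduce segment_days"
        )
    max_gap = int(config.max_gap_fill_h * 60 // s.interval_minutes)
    filled = _fill_short_gaps(x, valid, max_gap)
    finite = np.isfinite(filled)
    if not finite.any():
        raise ConfigError(f"site {s.site_id}: no usable samples for spectrum")
    total_var = float(np.nanvar(filled))

    step = max(int(round(nperseg * (1 - config.overlap_fraction))), 1)
    window = sig.get_window(config.window_shape, nperseg)  # periodic form
    u = float(np.sum(window**2))

    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs_cpd)
    acc = np.zeros(len(freqs))
    n_segments = 0
    n_dropped = 0
    for start in range(0, len(filled) - nperseg + 1, step):
        seg = filled[start:start + nperseg]
        if not np.all(np.isfinite(seg)):
            n_dropped += 1
            continue
        seg = _detrend(seg, config.detrend)
        spec = np.fft.rfft(window * seg)
        p = (np.abs(spec) ** 2) / (fs_cpd * u)
        p[1:] *= 2.0  # one-sided; DC not doubled
        if nperseg % 2 == 0:
            p[-1] /= 2.0  # Nyquist bin not doubled
        acc += p
        n_segments += 1
    if n_segments == 0:
        raise ConfigError(
            f"site {s.site_id}: every segment contained a gap longer than "
            f"{config.max_gap_fill_h} h; no spectrum"
        )
    if n_dropped:
        logger.info("site %s %s: dropped %d gappy segments", s.site_id, variable,
                    n_dropped)
    if n_segments < 4:
        logger.warning(
            "site %s %s: only %d Welch segments; spectral estimate is noisy",
            s.site_id, variable, n_segments,
        )
    psd = acc / n_segments

    # renormalise the density so that its integral equals the record variance
    raw_integral = float(np.trapezoid(psd, freqs))
    if raw_integral > 0 and total_var > 0:
        psd = psd * (total_var / raw_integral)
    elif total_var == 0:
        psd = np.zeros_like(psd)

    spectrum = BandSpectrum(
        site_id=s.site_id,
        variable=variable,
        frequencies_cpd=freqs,
        psd=psd,
        total_variance=total_var,
        n_segments=n_segments,
    )
    for name, (lo, hi) in BANDS_CPD.items():
        spectrum.band_variance[name] = integrate_band(spectrum, lo, hi)
    if any(v > 0 for v in spectrum.band_variance.values()):
        spectrum.dominant = dominant_band(spectrum)
    return spectrum


def integrate_band(spectrum: BandSpectrum, f_lo_cpd: float, f_hi_cpd: float) -> float:
    """Trapezoidal band integral of the density, with interpolated edges.

    Band edges are closed; density values at the exact edges are obtained
    by linear interpolation on the resolved frequency grid.
    """
    f, p = spectrum.frequencies_cpd, spectrum.psd
    if not 0 <= f_lo_cpd < f_hi_cpd:
        raise BandResolutionError(f"bad band [{f_lo_cpd}, {f_hi_cpd}]")
    if f_hi_cpd > f[-1] + 1e-12:
        raise BandResolutionError(
            f"band upper edge {f_hi_cpd} cpd exceeds the Nyquist frequency "
            f"{f[-1]:.4g} cpd"
        )
    inside = (f > f_lo_cpd) & (f < f_hi_cpd)
    nodes = np.concatenate(([f_lo_cpd], f[inside], [f_hi_cpd]))
    values = np.concatenate((
        [np.interp(f_lo_cpd, f, p)], p[inside], [np.interp(f_hi_cpd, f, p)],
    ))
    return float(np.trapezoid(values, nodes))


def dominant_band(spectrum: BandSpectrum, tie_rtol: float = 0.01) -> str:
    """Name of the band with the greatest integrated variance.

    Bands whose variance is within ``tie_rtol`` (relative) of the maximum
    are considered tied; ties resolve toward the lower-frequency band and
    are reported in the log.
    """
    bv = spectrum.band_variance
    if not bv:
        for name, (lo, hi) in BANDS_CPD.items():
            bv[name] = integrate_band(spectrum, lo, hi)
    vmax = max(bv.values())
    if vmax <= 0:
        raise UndefinedDominanceError(
            f"site {spectrum.site_id}: all band variances are zero"
        )
    tied = [name for name in BANDS_CPD if bv.get(name, 0.0) >= vmax * (1 - tie_rtol)]
    if len(tied) > 1:
        logger.info("site %s %s: dominant-band tie among %s, resolved to %s",
                    spectrum.site_id, spectrum.variable, tied, tied[0])
    return tied[0]
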