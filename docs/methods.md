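# Methods

This note records the models, conventions, and numerical choices behind
kelpox, and what the synthetic-data validation does and does not establish.

## Data model and QC

A site record is a paired (temperature, DO) series on a uniform nominal
grid (10 min for analysis; 1- and 5-min records are decimated by
*subsampling* — selecting the samples that fall on the coarser grid — not
by block averaging, so the analysis grid contains actual observations).
Timestamps are timezone-naive local instants; calendar operations (day,
month) use them directly. Clock jitter within ±1 min is snapped to the
grid; duplicate timestamps keep the first occurrence; both are counted in
log notices. Physical QC limits (DO 0–25 mg/L, T −5–45 °C, configurable)
flag samples invalid without dropping them. Validity is tracked per
variable: paired statistics (daily means, monthly correlations) require
both variables valid; DO-only statistics (events, CV, rate of change, DO
spectra) use the DO mask alone. `regularize` fills missing grid ticks with
invalid placeholders so downstream code can assume gapless arrays.

## Hypoxic events

An event is a maximal run of consecutive valid samples with DO ≤ θ
(θ = 2 mg/L by default; the comparator is configurable because both ≤ and
< appear in common usage) whose duration is at least 1 h. Conventions:

- **Duration** = (number of below-threshold samples) × grid interval. Each
  sample represents its sampling interval, so six 10-min samples = 1.0 h
  qualifies under "an hour or more".
- **Gap merging**: a dropout of invalid samples spanning ≤ 30 min
  (`max_gap_minutes`) between two below-threshold runs merges them — a
  brief sensor dropout inside one exposure should not split it. Any valid
  above-threshold sample separates events. Merged-event duration counts
  below-threshold samples only; start/end are the first/last
  below-threshold instants.
- **Return time** = start of next event − end of previous event, in hours;
  there are exactly *n*−1 return times for *n* ≥ 2 events. At sites whose
  events cluster in one season this mean is dominated by within-cluster
  spacing; no cross-season exclusion is applied.
- **Severe** events have min DO < 0.05 mg/L.
- Monthly event proportions attribute each event to the calendar month of
  its start; events are not split at month boundaries.

The detector is validated against an independently written pure-Python
maximal-run scanner on thousands of random gappy series (exact agreement).

## Exposure metrics

CV uses the sample (n−1) standard deviation by default (`cv_ddof`
configurable). The mean absolute rate of change averages |ΔDO|/Δt only
over adjacent valid pairs exactly one grid step apart; pairs spanning gaps
are excluded. Event-level means (duration, return time) are undefined —
reported as null, never zero — when no events (or fewer than two) occur.

## Monthly coupling

Pearson correlation (Spearman available) over all jointly valid 10-min
(T, DO) pairs per calendar month; raw samples rather than daily means are
used by default since aggregation would discard the sub-daily covariation
that upwelling pulses produce (a daily-mean switch can be emulated by
correlating the `daily_means` output). Months contribute only with ≥ 100
valid pairs (configurable), and months where either variable has zero
variance are omitted with a warning rather than reported as r = 0. The
0.7 line is treated as a classification threshold for "coupled", not as a
significance test, so no p-values are attached to monthly r. The depth
regression is ordinary least squares of a per-site summary metric on
sensor depth with the two-sided slope t-test (scipy `linregress`),
requiring ≥ 3 sites after dropping sites where the metric is undefined.

## Variance spectra

Welch estimate: 90-day segments (≈ 7 segments in a year at 50% overlap),
periodic Hamming taper, per-segment mean removal (linear detrend by
config), one-sided density on a cycles-per-day axis. The density is then
renormalised so its trapezoidal integral over frequency equals the
variance of the analyzed record — this makes Parseval consistency exact by
construction and puts sites with different record lengths on a common
variance scale. Against `scipy.signal.welch` on gapless records the
estimator agrees to rounding before that final rescaling.

Gaps ≤ 6 h are linearly interpolated; segments still containing longer
gaps are dropped from the average (interpolating long gaps would bias
high-frequency variance low). A warning is issued below 4 segments; a
record shorter than one segment yields a flagged null spectrum in the
pipeline rather than a failure.

Band integrals use trapezoidal quadrature with density values at the exact
band edges obtained by linear interpolation; edges are closed. With 90-day
segments the resolution is 1/90 ≈ 0.011 cpd, so the seasonal band
(0.01–0.05 cpd) contains only ~4 resolved frequencies: its integral is
computed but is coarse below ~0.02 cpd, and the annual cycle itself
(0.0027 cpd) sits below the band and reaches it only through leakage.
Dominant-band ties (within 1% relative, configurable) resolve toward the
lower-frequency band and are logged.

## Synthetic generator

Temperature = annual cosine with its minimum on 15 May (the record runs
1 Oct–30 Sep; cooling through winter/spring upwelling, warming in summer)
+ AR(1) red noise with a 4-day decorrelation time (mid-range of the 2–10
day synoptic band; the AR coefficient is exp(−Δt/τ)) + diurnal and
semidiurnal sinusoids + white noise. DO = base + α_m · T-anomaly (α_m per
calendar month; ≥ 0.7 marks a designed-coupled month) + its own diurnal /
semidiurnal oscillations + independent AR(1) excursions in designated
decoupled months (respiration-style drawdown) + white noise, clipped at 0.

Injected hypoxic excursions force DO to `min(DO, envelope)` where the
envelope descends from ambient to a floor through half-cosine ramps (1 h
each side) around a plateau of chosen duration. Because the envelope is
analytic, the exact sub-2 mg/L span of each event is recorded as ground
truth (truth describes the pre-noise record; a flag notes when clipping
occurred). Defaults: base DO 7 mg/L, base T 14 °C, seasonal amplitude
3 °C, synoptic σ 0.8 °C, diurnal/semidiurnal amplitudes 0.3/0.15 °C and
0.4/0.2 mg/L, observation noise σ 0.05 — values a nearshore mooring in an
upwelling system plausibly exhibits, chosen once and used everywhere.

The default 18-site region reuses the real deployment metadata (latitude,
longitude, depth) and arranges a designed exposure gradient: six northern
sites with no events; seven mid-region sites with 3–9 events, floors
around 1.2 mg/L, and spacings from three weeks down to days; five southern
sites with 40–72 severe (floor < 0.05 mg/L) events at sub-daily spacing.
Counts, durations, and spacings are strictly monotone southward so that
exposure *orderings* are recoverable exactly, and spring months (Mar–May)
are designed coupled at every site while summers are decoupled.

**What passing does not show.** The generator has no internal-bore or
tidal-harmonic physics, no sensor drift or biofouling, no bloom forcing,
and its gaps are injected rather than instrument-driven; recovery of its
ground truth validates the analysis pipeline's correctness, not the
oceanographic fidelity of any particular real-site result.

## Problem sizes

The verification script and acceptance tests use: 1,000 random series of
200–2,000 samples for oracle equivalence; 20 year-long records for
Parseval; one year-long record for band-amplitude recovery; the 18-site
region once for ordering recovery and over 50 seeds (10,800 site-months)
for coupling classification; 100 replicates of the 18-site depth
regression. All sizes match the study's structure (18 sites × 1 year at
10 min) except where a property is intrinsically per-record.
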