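# kelpox

Analysis of year-long nearshore temperature and dissolved-oxygen (DO)
sensor time series: hypoxic-event detection and exposure metrics, monthly
temperature–oxygen coupling, and band-integrated variance spectra — with a
synthetic multi-site generator that provides ground truth for end-to-end
validation.

## Who it is for

Coastal ecologists and monitoring networks running moored oxygen/temperature
loggers (e.g. PME MiniDOT, Seabird SBE37) in kelp-forest and rocky-reef
habitats, who need comparable per-site exposure statistics across a region:
how often does DO fall below the hypoxia threshold, for how long, how fast
does it return, and is the drawdown driven by upwelling or by respiration?

## What it computes

**Hypoxia exposure.** A hypoxic event is a maximal run of consecutive valid
10-min samples with DO ≤ 2 mg/L lasting ≥ 1 h (six samples); events with
min DO < 0.05 mg/L are *severe* (near-anoxic). Per site: mean/max
temperature, minimum DO, the coefficient of variation CV = σ(DO)/μ(DO), the
mean absolute rate of change ⟨|ΔDO|/Δt⟩ over adjacent samples, event count
*n*, mean event duration, mean return time (end of one event to the start
of the next), and the monthly distribution of event starts.

**Coupling.** For each calendar month, the Pearson correlation *r* between
paired T and DO samples. Months with *r* ≥ 0.7 are classified as
upwelling-coupled (cold, low-oxygen water arriving together); low-*r*
months with DO drawdown indicate respiration-driven (decoupled) hypoxia.
Daily means supply the T–DO biplot trajectory, and OLS of minimum DO (or
any other exposure metric) on sensor depth checks for depth confounding.

**Timescales.** Welch variance spectra (90-day Hamming segments, 50%
overlap), renormalised so that ∫S(f) df equals the record variance, are
integrated over seasonal (0.01–0.05 cpd), synoptic (0.1–0.5 cpd), diurnal
(0.75–1.25 cpd), and semidiurnal (1.75–2.25 cpd) bands; the band with the
largest integrated variance is the record's dominant timescale.

## Worked example

```python
import kelpox as kx

scenario = kx.SiteScenario(
    site_id="DEMO", seed=11, noise_sd=0.0,
    event_schedule=(
        kx.EventSpec("2018-06-10T03:00", 4.0, 0.8),
        kx.EventSpec("2018-07-02T12:00", 2.0, 0.02),
    ),
)
series, truth = kx.generate_site(scenario)
for e in kx.detect_hypoxic_events(series):
    print(e.start, round(e.duration_h, 2), round(e.min_do_mgL, 2), e.severe)
```

prints

```
2018-06-10 03:50:00 4.5 0.8 False
2018-07-02 12:40:00 2.83 0.02 True
```

Each line is one detected hypoxic event: its first sub-threshold sample,
its duration in hours (longer than the injected 4 h / 2 h plateaus because
the ramps also spend time below 2 mg/L), its minimum DO, and the severe
flag for the near-anoxic second event. More walkthroughs — regional
exposure gradients, monthly coupling classification, variance spectra, the
full pipeline — are in `examples/`.

The same pipeline runs from the shell over a directory of per-site CSVs:

```bash
kelpox synthesize --out data --seed 5
kelpox analyze --input data --sites data/sites.csv --out results
```

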