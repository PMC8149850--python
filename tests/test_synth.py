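"""Generator ground truth, determinism, and analysis recovery."""

import numpy as np
import pandas as pd
import pytest

from kelpox.coupling import monthly_correlations
from kelpox.errors import ValidationError
from kelpox.events import detect_hypoxic_events, summarize_exposure
from kelpox.series import regularize
from kelpox.spectra import welch_variance_spectrum
from kelpox.synth import (
    EventSpec, SiteScenario, corrupt, default_region_scenarios,
    default_site_table, generate_region, generate_site, load_scenarios,
    write_region,
)


def _noiseless_event_scenario(events, **kw):
    return SiteScenario(
        site_id="EVT", seed=9, noise_sd=0.0, synoptic_sd=0.0,
        t_diurnal_amp=0.0, t_semidiurnal_amp=0.0, do_diurnal_amp=0.0,
        do_semidiurnal_amp=0.0, decouple_months=(), decoupled_do_sd=0.0,
        event_schedule=tuple(events), **kw,
    )


class TestGenerateSite:
    def test_reproducible_bitwise(self):
        sc = SiteScenario(site_id="A", seed=42)
        s1, _ = generate_site(sc)
        s2, _ = generate_site(SiteScenario(site_id="A", seed=42))
        np.testing.assert_array_equal(s1.do_mgL, s2.do_mgL)
        np.testing.assert_array_equal(s1.temperature_C, s2.temperature_C)
        s3, _ = generate_site(SiteScenario(site_id="A", seed=43))
        assert not np.array_equal(s1.do_mgL, s3.do_mgL)

    def test_all_zero_amplitudes_give_constant_record(self):
        sc = _noiseless_event_scenario([], seasonal_amp_C=0.0)
        s, truth = generate_site(sc)
        np.testing.assert_allclose(s.temperature_C, sc.base_temp_C)
        np.testing.assert_allclose(s.do_mgL, sc.base_do_mgL)
        assert truth.n_events == 0 and not truth.clipped

    def test_single_event_recovered_exactly(self):
        sc = _noiseless_event_scenario(
            [EventSpec("2018-06-01T00:00", 3.0, 0.5)])
        s, truth = generate_site(sc)
        evts = detect_hypoxic_events(s)
        assert len(evts) == 1 == truth.n_events
        t = truth.events[0]
        assert t.below_duration_h >= 3.0  # ramps extend the sub-2 span
        assert abs(evts[0].duration_h - t.below_duration_h) <= 10 / 60
        assert evts[0].min_do_mgL == pytest.approx(0.5, abs=1e-9)
        assert not evts[0].severe and not t.severe

    def test_event_schedule_validation(self):
        with pytest.raises(ValidationError, match="overlap"):
            _noiseless_event_scenario([
                EventSpec("2018-06-01T00:00", 5.0, 0.5),
                EventSpec("2018-06-01T03:00", 5.0, 0.5),
            ])
        with pytest.raises(ValidationError, match="floor"):
            _noiseless_event_scenario([EventSpec("2018-06-01", 3.0, 9.0)])

    def test_event_recovery_with_many_events(self):
        events = [EventSpec(f"2018-07-{d:02d}T06:00", 2.0, 0.02)
                  for d in range(1, 21)]
        sc = _noiseless_event_scenario(events)
        s, truth = generate_site(sc)
        evts = detect_hypoxic_events(s)
        assert len(evts) == truth.n_events == 20
        assert all(e.severe for e in evts)
        mean_det = np.mean([e.duration_h for e in evts])
        assert abs(mean_det - truth.mean_duration_h) <= 10 / 60
        det_rt = np.mean([
            (b.start - a.end) / pd.Timedelta(hours=1)
            for a, b in zip(evts, evts[1:])
        ])
        assert abs(det_rt - truth.mean_return_time_h) <= 2 * 10 / 60

    def test_coupled_month_exceeds_threshold(self):
        hits = 0
        for seed in range(10):
            sc = SiteScenario(site_id="C", seed=seed, decouple_months=(),
                              decoupled_do_sd=0.0)
            s, truth = generate_site(sc)
            for mc in monthly_correlations(s):
                if truth.coupled_by_month[mc.year_month.month]:
                    hits += mc.r > 0.7
        assert hits >= 0.95 * 10 * 5  # 5 designed-coupled months per year

    def test_band_amplitude_recovery_from_truth(self):
        sc = SiteScenario(site_id="B", seed=2, synoptic_sd=0.2,
                          do_diurnal_amp=0.6, do_semidiurnal_amp=0.3,
                          coupling_by_month={m: 0.0 for m in range(1, 13)},
                          decouple_months=(), decoupled_do_sd=0.0)
        s, truth = generate_site(sc)
        spec = welch_variance_spectrum(s)
        for band in ("diurnal", "semidiurnal"):
            amp = truth.band_amplitudes[band]["do"]
            assert spec.band_variance[band] == pytest.approx(
                amp**2 / 2, rel=0.10)


class TestRegion:
    def test_empty_and_duplicate_site_lists_rejected(self):
        with pytest.raises(ValidationError):
            generate_region([])
        sc = SiteScenario(site_id="X")
        with pytest.raises(ValidationError):
            generate_region([sc, SiteScenario(site_id="X", seed=1)])

    def test_default_region_gradient_recovered(self):
        scenarios = default_region_scenarios(seed=0)
        region = generate_region(scenarios)
        assert len(region) == 18
        counts, durations, returns = [], [], []
        for sc in scenarios:
            series, truth = region[sc.site_id]
            evts = detect_hypoxic_events(series)
            assert len(evts) == truth.n_events
            counts.append(len(evts))
            summ = summarize_exposure(series, evts)
            durations.append(summ.mean_duration_h)
            returns.append(summ.mean_return_time_h)
        assert counts[:6] == [0] * 6           # northern sites never hypoxic
        south = counts[13:]
        assert all(c >= 40 for c in south)
        # designed monotone north-to-south ordering among event-bearing sites
        assert counts[6:] == sorted(counts[6:])
        assert durations[6:] == sorted(durations[6:])
        with_rt = [r for r in returns if r is not None]
        assert with_rt == sorted(with_rt, reverse=True)
        assert all(r < 24 for r in returns[13:])  # sub-daily in the south

    def test_site_table_matches_region_ids(self):
        table = default_site_table()
        assert [s.site_id for s in table][:2] == ["1-VD", "2-MRY"]
        assert len({s.site_id for s in table}) == 18


class TestCorrupt:
    def test_no_corruption_is_identity(self):
        s, _ = generate_site(SiteScenario(site_id="A", seed=1))
        c = corrupt(s)
        np.testing.assert_array_equal(c.do_mgL, s.do_mgL)
        assert len(c) == len(s)

    def test_two_hour_hole_regularizes_to_12_inserted(self):
        s, _ = generate_site(SiteScenario(site_id="A", seed=1))
        c = corrupt(s, gaps=[("2018-02-01T00:00", 120)])
        assert len(c) == len(s) - 12
        r = regularize(c)
        assert len(r) == len(s)
        assert int((~r.do_valid).sum()) == 12

    def test_hole_inside_event_still_one_merged_event(self):
        sc = _noiseless_event_scenario(
            [EventSpec("2018-06-01T00:00", 3.0, 0.5)])
        s, _ = generate_site(sc)
        c = corrupt(s, gaps=[("2018-06-01T02:00", 30)])
        evts = detect_hypoxic_events(c)
        assert len(evts) == 1

    def test_invalid_value_injection(self):
        s, _ = generate_site(SiteScenario(site_id="A", seed=1))
        c = corrupt(s, invalid_values=[("2018-02-01T00:00", "do", -5.0)])
        i = c.timestamps.get_indexer([pd.Timestamp("2018-02-01T00:00")])[0]
        assert not c.do_valid[i] and c.do_mgL[i] == -5.0


class TestScenarioFiles:
    def test_yaml_roundtrip(self, tmp_path):
        f = tmp_path / "region.yaml"
        f.write_text(
            "defaults:\n  noise_sd: 0.0\n  seed: 5\n"
            "sites:\n"
            "  - site_id: N1\n"
            "  - site_id: S1\n"
            "    events:\n"
            "      - ['2018-06-01T00:00', 3.0, 0.5]\n"
            "    decouple_months: [7, 8]\n"
        )
        scenarios = load_scenarios(f)
        assert [s.site_id for s in scenarios] == ["N1", "S1"]
        assert scenarios[1].event_schedule[0].floor_mgL == 0.5
        assert scenarios[1].decouple_months == (7, 8)

    def test_write_region_layout(self, tmp_path):
        scenarios = [SiteScenario(site_id="1-VD", seed=1, n_days=2)]
        region = generate_region(scenarios)
        write_region(region, tmp_path)
        assert (tmp_path / "1-VD.csv").exists()
        assert (tmp_path / "sites.csv").exists()
        assert (tmp_path / "truth.json").exists()
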