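"""Generator correctness: curve phantoms, image phantoms, cohorts."""

import dataclasses

import numpy as np
import pytest

from pulmotransit.extraction import extract_aif
from pulmotransit.synthetic import (CohortConfig, PhantomGeometry,
                                    TransitPhantomConfig, generate_aif_pair,
                                    generate_cohort, generate_dynamic_series)


class TestAifPair:
    def test_rv_centroid_matches_gamma_variate_closed_form(self):
        # first moment of A*(t-t0)^a*exp(-(t-t0)/b) is t0 + b*(a+1) = 4 + 2*4 = 12 s
        cfg = TransitPhantomConfig(alpha=3.0, beta=2.0, t0_rv=4.0,
                                   noise_sd=0.0, recirc_fraction=0.0, seed=0)
        _, truth = generate_aif_pair(cfg)
        assert truth.true_centroid_rv == pytest.approx(12.0, abs=1e-3)

    def test_pure_delay_kernel_shifts_lv_by_transit_mean(self, clean_config):
        pair, truth = generate_aif_pair(clean_config)
        assert truth.true_ptt == pytest.approx(clean_config.transit_mean, abs=1e-3)
        # sampled LV curve is the RV curve evaluated transit_mean later
        shift_frames = clean_config.transit_mean / clean_config.rr_interval
        assert truth.true_pttn == pytest.approx(shift_frames, abs=1e-3)

    @pytest.mark.parametrize("dispersion", [0.5, 1.0, 2.0])
    def test_centroid_difference_equals_kernel_mean_for_any_dispersion(self, dispersion):
        # convolution with a normalized kernel adds the kernel mean to the centroid
        cfg = TransitPhantomConfig(transit_dispersion=dispersion, noise_sd=0.0,
                                   recirc_fraction=0.0, seed=0)
        _, truth = generate_aif_pair(cfg)
        assert truth.true_ptt == pytest.approx(cfg.transit_mean, abs=5e-3)
        assert truth.true_centroid_lv == pytest.approx(
            truth.true_centroid_rv + cfg.transit_mean, abs=5e-3)

    def test_same_seed_is_bitwise_reproducible(self, realistic_config):
        p1, _ = generate_aif_pair(realistic_config)
        p2, _ = generate_aif_pair(realistic_config)
        assert np.array_equal(p1.rv.conc, p2.rv.conc)
        assert np.array_equal(p1.lv.conc, p2.lv.conc)

    def test_different_seed_changes_noise(self):
        p1, _ = generate_aif_pair(TransitPhantomConfig(seed=1))
        p2, _ = generate_aif_pair(TransitPhantomConfig(seed=2))
        assert not np.array_equal(p1.rv.conc, p2.rv.conc)

    def test_uncaptured_first_pass_rejected(self):
        cfg = TransitPhantomConfig(n_frames=30, transit_mean=15.0)
        with pytest.raises(ValueError, match="first pass not captured"):
            generate_aif_pair(cfg)

    @pytest.mark.parametrize("field,value", [
        ("recirc_fraction", 1.0), ("recirc_fraction", -0.1),
        ("transit_mean", 0.0), ("rr_interval", 0.0), ("n_frames", 10),
    ])
    def test_invalid_config_rejected(self, field, value):
        cfg = dataclasses.replace(TransitPhantomConfig(), **{field: value})
        with pytest.raises(ValueError):
            generate_aif_pair(cfg)

    def test_recirculation_raises_late_tail_only(self):
        base = TransitPhantomConfig(noise_sd=0.0, recirc_fraction=0.0, seed=0)
        with_rc = dataclasses.replace(base, recirc_fraction=0.4)
        p0, _ = generate_aif_pair(base)
        p1, _ = generate_aif_pair(with_rc)
        t = p0.times
        early = t < base.t0_rv + base.recirc_delay
        assert np.allclose(p0.rv.conc[early], p1.rv.conc[early])
        assert p1.rv.conc[~early].sum() > p0.rv.conc[~early].sum()


class TestDynamicSeries:
    def test_noiseless_cavity_mean_reproduces_signal_curve(self, realistic_config):
        from pulmotransit.saturation import HyperbolicSaturation
        calib = HyperbolicSaturation()
        series, masks = generate_dynamic_series(realistic_config, calib=calib)
        noiseless = dataclasses.replace(realistic_config, noise_sd=0.0)
        pair, _ = generate_aif_pair(noiseless)
        rv_mean = series.frames[:, masks.rv_mask].mean(axis=1)
        expected = calib.s0 * (1.0 + calib.forward(pair.rv.conc))
        assert np.allclose(rv_mean, expected)

    def test_rv_time_to_peak_precedes_lv(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            rr = rng.uniform(0.7, 1.1)
            cfg = TransitPhantomConfig(
                transit_mean=rng.uniform(2.5 * rr, 15.0),
                transit_dispersion=rng.uniform(0.0, 1.5),
                rr_interval=rr, noise_sd=0.0, seed=int(rng.integers(1 << 30)))
            series, masks = generate_dynamic_series(cfg)
            rv_sig = series.frames[:, masks.rv_mask].mean(axis=1)
            lv_sig = series.frames[:, masks.lv_mask].mean(axis=1)
            assert np.argmax(rv_sig) < np.argmax(lv_sig)

    def test_overlapping_cavities_rejected(self, realistic_config):
        geom = PhantomGeometry(rv_center=(32, 30), lv_center=(32, 36))
        with pytest.raises(ValueError, match="overlap"):
            generate_dynamic_series(realistic_config, geometry=geom)

    def test_degenerate_frame_count_rejected(self):
        with pytest.raises(ValueError):
            generate_dynamic_series(TransitPhantomConfig(n_frames=0))

    def test_extraction_round_trip_on_noiseless_phantom(self, realistic_config):
        # render then extract: recovered concentrations match the generator
        series, masks = generate_dynamic_series(realistic_config)
        pair = extract_aif(series, masks)
        noiseless = dataclasses.replace(realistic_config, noise_sd=0.0)
        gen_pair, _ = generate_aif_pair(noiseless)
        assert np.allclose(pair.rv.conc, gen_pair.rv.conc, atol=1e-6)
        assert np.allclose(pair.lv.conc, gen_pair.lv.conc, atol=1e-6)


class TestCohort:
    def test_seeded_determinism(self, small_cohort_config):
        a = generate_cohort(small_cohort_config)
        b = generate_cohort(small_cohort_config)
        assert a.equals(b)

    def test_full_censoring_yields_zero_events(self):
        df = generate_cohort(CohortConfig(n_subjects=300, censor_rate=1.0, seed=1))
        assert df["event"].sum() == 0

    def test_event_count_increases_with_hazard_scale(self):
        counts = [
            generate_cohort(CohortConfig(n_subjects=3000, seed=5,
                                         baseline_hazard_scale=s))["event"].sum()
            for s in (0.001, 0.0024, 0.006)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_log_ptt_sign_structure_matches_generating_betas(self):
        # negative betas (LVEF, heart rate, diabetes, hypertension) and positive
        # (age, male, AF, LA area) must show up as signed rank correlations
        from scipy.stats import spearmanr
        df = generate_cohort(CohortConfig(n_subjects=2000, seed=9))
        for col, sign in [("lvef", -1), ("heart_rate", -1), ("diabetes", -1),
                          ("hypertension", -1), ("age", 1), ("male", 1),
                          ("atrial_fibrillation", 1), ("la_area_index", 1)]:
            rho, _ = spearmanr(df[col], df["ptt"])
            assert np.sign(rho) == sign, f"{col}: rho={rho:.3f}"

    def test_pbvi_consistent_with_hemodynamic_chain(self):
        from pulmotransit.hemodynamics import derive_record
        df = generate_cohort(CohortConfig(n_subjects=50, seed=3))
        row = df.iloc[17]
        rec = derive_record(row.stroke_volume, row.heart_rate, row.height,
                            row.weight, row.ptt)
        assert row.pbvi == pytest.approx(rec.pbvi, rel=1e-12)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(n_subjects=1))
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(age=(62.0, -1.0)))
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(baseline_hazard_scale=0.0))
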