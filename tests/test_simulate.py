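"""Generators: determinism, envelope compliance, noiseless identities."""

import numpy as np
import pytest

from coralmeta import (
    ExperimentSimSpec,
    SSTSimSpec,
    activation_energy,
    detect_events,
    gen_experiments,
    gen_factorial,
    gen_sst,
    interaction_effect,
    lnrr_co2,
    percentile_threshold,
)


class TestGenExperiments:
    def test_same_seed_reproduces(self):
        spec = ExperimentSimSpec(n_studies=5, seed=11)
        r1, t1 = gen_experiments(spec)
        r2, t2 = gen_experiments(spec)
        assert r1 == r2
        assert t1.equals(t2)

    def test_study_count(self):
        spec = ExperimentSimSpec(n_studies=40, seed=0)
        records, _ = gen_experiments(spec)
        assert len({r.study_id for r in records}) == 40

    def test_noiseless_records_recover_true_effects_exactly(self):
        spec = ExperimentSimSpec(
            n_studies=10, noise_cv=0.0, between_study_sd=0.0,
            between_genus_sd=0.0, seed=2,
            true_E_by_attribute={"survival": 0.7},
            true_lnrr100_by_attribute={"calcification": -0.0197},
        )
        records, truth = gen_experiments(spec)
        for rec, row in zip(records, truth.itertuples()):
            if rec.arm_type == "warming":
                assert activation_energy(rec).value == pytest.approx(0.7, rel=1e-10)
            else:
                assert lnrr_co2(rec).value == pytest.approx(-0.0197, rel=1e-10)
            assert row.latent_value == row.true_value

    def test_envelopes_respect_design_ranges(self):
        spec = ExperimentSimSpec(n_studies=40, effects_per_study=3, seed=4)
        records, _ = gen_experiments(spec)
        for r in records:
            if r.arm_type == "warming":
                assert 24.0 <= r.t_control_C <= 30.0
                assert 0.5 <= r.delta_T_C <= 13.0
            else:
                assert 297.0 <= r.pco2_control_uatm <= 486.0
                assert 100.0 <= r.delta_pco2_uatm <= 800.0
            assert spec.arm_n_range[0] <= r.control_n <= spec.arm_n_range[1]

    def test_truth_table_supports_downstream_expectations(self):
        """Latent values in the truth table reproduce the record-level effect
        without re-running the generator (exact when sampling is off)."""
        spec = ExperimentSimSpec(n_studies=6, noise_cv=0.1,
                                 between_study_sd=0.3, seed=9)
        records, truth = gen_experiments(spec, sampling=False)
        for rec, row in zip(records, truth.itertuples()):
            es = (activation_energy(rec) if rec.arm_type == "warming"
                  else lnrr_co2(rec))
            assert es.value == pytest.approx(row.latent_value, rel=1e-9)


class TestGenFactorial:
    def test_multiplicative_null_without_sampling_is_exact_zero(self):
        spec = ExperimentSimSpec(noise_cv=0.1, seed=1)
        quads, truth = gen_factorial(spec, interaction_magnitude=0.0,
                                     n_quads=5, sampling=False)
        for q in quads:
            assert interaction_effect(q).lnrr_inter == pytest.approx(0.0, abs=1e-12)
        assert (truth["interaction_magnitude"] == 0.0).all()

    def test_negative_magnitude_with_tiny_noise_is_synergistic(self):
        spec = ExperimentSimSpec(noise_cv=0.01, seed=3)
        quads, _ = gen_factorial(spec, interaction_magnitude=-0.5, n_quads=5,
                                 sampling=False)
        for q in quads:
            r = interaction_effect(q, variance_mode="delta")
            assert r.lnrr_warming < 0 and r.lnrr_pco2 < 0
            assert r.classification == "synergistic"

    def test_positive_magnitude_with_tiny_noise_is_antagonistic(self):
        spec = ExperimentSimSpec(noise_cv=0.01, seed=3)
        quads, _ = gen_factorial(spec, interaction_magnitude=0.5, n_quads=5,
                                 sampling=False)
        for q in quads:
            r = interaction_effect(q, variance_mode="delta")
            assert r.lnrr_warming < 0 and r.lnrr_pco2 < 0
            assert r.classification == "antagonistic"


class TestGenSST:
    def test_same_seed_identical_series(self):
        spec = SSTSimSpec(years=4, baseline_years=2, noise_sd_C=0.5,
                          ar1_coeff=0.5, seed=8)
        s1, _ = gen_sst(spec)
        s2, _ = gen_sst(spec)
        assert np.array_equal(s1.sst, s2.sst)

    def test_noiseless_injection_detected_exactly(self):
        spec = SSTSimSpec(years=3, baseline_years=1, seasonal_amplitude_C=0.0,
                          noise_sd_C=0.0, injected_events=[(500, 7, 2.0)],
                          truth_percentile=90.0, seed=0)
        series, truth = gen_sst(spec)
        thr = percentile_threshold(series, 90)
        events = detect_events(series, thr)
        assert len(events) == 1
        assert events[0].duration_days == 7
        # flat noiseless baseline: threshold equals the mean, intensity is
        # the full injected amplitude
        assert thr == pytest.approx(spec.mean_C)
        assert events[0].max_intensity_C == pytest.approx(2.0)
        assert truth.loc[0, "expected_exceedance_days"] == 7
        assert truth.loc[0, "expected_max_intensity_C"] == pytest.approx(2.0)

    def test_no_injection_noiseless_no_events(self):
        # flat noiseless series: threshold equals the constant, and strict
        # exceedance means no event at any percentile
        spec = SSTSimSpec(years=2, baseline_years=1, seasonal_amplitude_C=0.0,
                          noise_sd_C=0.0, seed=0)
        series, _ = gen_sst(spec)
        thr = percentile_threshold(series, 99)
        assert detect_events(series, thr) == []

    def test_noleap_calendar(self):
        spec = SSTSimSpec(years=5, baseline_years=1, start_year=2000, seed=0)
        series, _ = gen_sst(spec)
        assert len(series.sst) == 5 * 365
        assert not ((series.dates.month == 2) & (series.dates.day == 29)).any()

    def test_trend_starts_after_baseline(self):
        spec = SSTSimSpec(years=4, baseline_years=2, trend_C_per_decade=1.0,
                          noise_sd_C=0.0, seed=0)
        series, _ = gen_sst(spec)
        baseline = series.sst[: 2 * 365]
        assert np.allclose(baseline, spec.mean_C)
        assert series.sst[-1] > spec.mean_C
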