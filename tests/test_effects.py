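"""Effect-size math: activation energy, CO2 log response ratio, variances."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coralmeta import (
    activation_energy,
    compute_effect_sizes,
    delta_inv_kT,
    effect_variance,
    lnrr_co2,
    quad_to_records,
)
from coralmeta.errors import DegenerateContrastError, DomainError, InsufficientDataError


class TestActivationEnergy:
    def test_hand_computed_example(self, warming_record):
        es = activation_energy(warming_record)
        assert es.delta_inv_kT == pytest.approx(0.25618, abs=1e-5)
        assert es.value == pytest.approx(0.22314 / 0.25618, abs=1e-4)

    def test_equal_rates_give_zero(self, warming_record):
        rec = dataclasses.replace(warming_record, treatment_mean=10.0)
        assert activation_energy(rec).value == 0.0

    def test_arm_swap_symmetry(self, warming_record):
        swapped = dataclasses.replace(
            warming_record,
            control_mean=warming_record.treatment_mean,
            treatment_mean=warming_record.control_mean,
            t_control_C=warming_record.t_treatment_C,
            t_treatment_C=warming_record.t_control_C,
        )
        assert activation_energy(swapped).value == pytest.approx(
            activation_energy(warming_record).value, rel=1e-12)

    def test_monotone_decreasing_in_treatment_mean(self, warming_record):
        values = [
            activation_energy(
                dataclasses.replace(warming_record, treatment_mean=vi)).value
            for vi in (12.0, 10.0, 8.0, 6.0)
        ]
        assert values == sorted(values)

    def test_nonpositive_mean_raises(self, warming_record):
        rec = dataclasses.replace(warming_record, treatment_mean=-1.0)
        with pytest.raises(DomainError):
            activation_energy(rec)

    def test_zero_temperature_contrast_raises(self, warming_record):
        rec = dataclasses.replace(
            warming_record, t_treatment_C=warming_record.t_control_C)
        with pytest.raises(DegenerateContrastError):
            activation_energy(rec)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        true_e=st.floats(0.1, 3.0),
        t0=st.floats(24.0, 30.0),
        dt=st.floats(0.5, 13.0),
        m0=st.floats(1.0, 100.0),
    )
    def test_exact_arrhenius_decline_recovers_true_e(self, true_e, t0, dt, m0):
        """Noiseless oracle: a record built with an exact Arrhenius decline
        returns the constructed E regardless of temperatures and scale."""
        d = delta_inv_kT(t0, t0 + dt)
        rec = dataclasses.replace(
            _record(m0, m0 * math.exp(-true_e * d)), t_control_C=t0,
            t_treatment_C=t0 + dt)
        assert activation_energy(rec).value == pytest.approx(true_e, rel=1e-9)


def _record(control_mean, treatment_mean):
    from coralmeta import ExperimentRecord
    return ExperimentRecord(
        "s", "g", "survival", "warming",
        control_mean, 1.0, 4, treatment_mean, 1.0, 4,
        t_control_C=26.0, t_treatment_C=29.0,
    )


class TestLnRRCO2:
    def test_hand_computed_example(self, co2_record):
        es = lnrr_co2(co2_record)
        assert es.value == pytest.approx(math.log(0.9) / 400 * 100, rel=1e-12)
        assert es.value == pytest.approx(-0.026341, abs=1e-6)

    def test_equal_means_give_zero(self, co2_record):
        rec = dataclasses.replace(co2_record, treatment_mean=10.0)
        assert lnrr_co2(rec).value == 0.0

    def test_doubling_delta_halves_value(self, co2_record):
        wider = dataclasses.replace(co2_record, pco2_treatment_uatm=1200.0)
        assert lnrr_co2(wider).value == pytest.approx(
            lnrr_co2(co2_record).value / 2.0, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_under_common_rescaling(self, scale):
        from coralmeta import ExperimentRecord
        co2_record = ExperimentRecord(
            "s2", "Porites", "calcification", "co2", 10.0, 1.0, 4, 9.0, 1.0, 4,
            pco2_control_uatm=400.0, pco2_treatment_uatm=800.0)
        scaled = dataclasses.replace(
            co2_record,
            control_mean=co2_record.control_mean * scale,
            treatment_mean=co2_record.treatment_mean * scale,
            control_sd=co2_record.control_sd * scale,
            treatment_sd=co2_record.treatment_sd * scale,
        )
        assert lnrr_co2(scaled).value == pytest.approx(
            lnrr_co2(co2_record).value, rel=1e-12)


class TestEffectVariance:
    def test_hand_computed_example(self, warming_record):
        # equal arms m=10, SD=1, n=4: v_ln = 2/(4*100) = 0.005
        rec = dataclasses.replace(warming_record, treatment_mean=10.0)
        v, floored = effect_variance(rec, "arrhenius_E")
        assert not floored
        assert v == pytest.approx(0.005 / 0.25618 ** 2, rel=1e-4)
        assert v == pytest.approx(0.07619, abs=2e-5)

    def test_lnrr_scaling(self, co2_record):
        v, _ = effect_variance(co2_record, "lnrr_co2")
        v_ln = 1.0 / (4 * 81.0) + 1.0 / (4 * 100.0)
        assert v == pytest.approx(v_ln * (100.0 / 400.0) ** 2, rel=1e-12)
        assert v == pytest.approx(v_ln / 16.0, rel=1e-12)

    def test_zero_sds_hit_floor_and_flag(self, warming_record):
        rec = dataclasses.replace(warming_record, control_sd=0.0, treatment_sd=0.0)
        v, floored = effect_variance(rec, "arrhenius_E", variance_floor=1e-8)
        assert floored and v == 1e-8

    def test_single_replicate_raises(self, warming_record):
        rec = dataclasses.replace(warming_record, control_n=1)
        with pytest.raises(InsufficientDataError):
            effect_variance(rec, "arrhenius_E")


class TestQuadDecomposition:
    def test_contexts_and_contrasts(self, simple_quad):
        w, c, w_oa, c_warm = quad_to_records(simple_quad)
        assert (w.arm_type, w.co_stressor) == ("warming", False)
        assert (w_oa.arm_type, w_oa.co_stressor) == ("warming", True)
        assert w_oa.control_mean == simple_quad.co2.mean
        assert w_oa.treatment_mean == simple_quad.both.mean
        assert c_warm.control_mean == simple_quad.warming.mean
        es = activation_energy(w_oa)
        assert es.context == "under_co_stressor"
        assert lnrr_co2(c_warm).context == "under_co_stressor"

    def test_tidy_table_covers_all_contrasts(self, warming_record, co2_record,
                                             simple_quad):
        df = compute_effect_sizes([warming_record, co2_record], [simple_quad])
        # 2 single records + 4 contrasts per quad
        assert len(df) == 6
        assert set(df["kind"]) == {"arrhenius_E", "lnrr_co2"}
        assert (df[df["context"] == "under_co_stressor"].shape[0]) == 2
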