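"""Back-transformation, the dT -> Delta(1/kT) map, and sensitivity scans."""

import dataclasses

import numpy as np
import pytest

from coralmeta import (
    ArrheniusMap,
    ExperimentRecord,
    MetaResult,
    ScenarioSpec,
    activation_energy,
    delta_inv_kT,
    fit_arrhenius_map,
    min_significant_delta,
    percent_change_co2,
    percent_change_temp,
    project_all,
)
from coralmeta.errors import DomainError


def _meta(estimate, se, kind="arrhenius_E", attribute="survival"):
    z = 1.959963984540054
    return MetaResult(
        estimate=estimate, se=se, ci_low=estimate - z * se,
        ci_high=estimate + z * se, p_value=0.5, sigma2_study=0.0,
        sigma2_genus=0.0, k=10, kind=kind, attribute=attribute,
    )


ANALYTIC_27 = ArrheniusMap(source="analytic_at_baseline", baseline_T_C=27.0)


class TestArrheniusMap:
    def test_analytic_value_at_one_degree(self):
        assert ANALYTIC_27.delta(1.0) == pytest.approx(0.12840, abs=2e-5)

    def test_fallback_to_analytic_when_no_records(self):
        amap = fit_arrhenius_map([], baseline_temperature_C=27.0)
        assert amap.source == "analytic_at_baseline"
        assert amap.delta(1.0) == pytest.approx(ANALYTIC_27.delta(1.0))

    def test_fitted_line_tracks_analytic_curve(self):
        records = [
            ExperimentRecord("s", "g", "survival", "warming", 10, 1, 4, 8, 1, 4,
                             t_control_C=27.0, t_treatment_C=27.0 + dt)
            for dt in np.linspace(0.5, 5.0, 10)
        ]
        amap = fit_arrhenius_map(records)
        assert amap.source == "fitted_from_data"
        assert amap.slope > 0
        # the exact relation is mildly concave in dT, so the OLS line matches
        # the analytic curve to the curvature scale, and exactly at tiny dT
        for dt in np.linspace(0.5, 5.0, 7):
            assert amap.delta(dt) == pytest.approx(ANALYTIC_27.delta(dt),
                                                   abs=5e-3)
        tight = [dataclasses.replace(r, t_treatment_C=27.0 + dt)
                 for r, dt in zip(records, np.linspace(0.001, 0.01, 10))]
        amap_tight = fit_arrhenius_map(tight)
        for dt in (0.002, 0.005, 0.01):
            assert amap_tight.delta(dt) == pytest.approx(ANALYTIC_27.delta(dt),
                                                         abs=1e-6)

    def test_identical_increments_singular(self):
        records = [
            ExperimentRecord("s", "g", "survival", "warming", 10, 1, 4, 8, 1, 4,
                             t_control_C=26.0, t_treatment_C=29.0)
        ] * 3
        with pytest.raises(DomainError):
            fit_arrhenius_map(records)


class TestPercentChange:
    def test_zero_effect_zero_change(self):
        est = percent_change_temp(_meta(0.0, 0.1), 5.0, ANALYTIC_27)
        assert est.percent_change == 0.0
        assert percent_change_co2(_meta(0.0, 0.1, kind="lnrr_co2"), 490.0
                                  ).percent_change == 0.0

    def test_printed_survival_declines(self):
        """E = 0.7 eV at the late-century high-emissions MHW rise (+4.32 C)
        gives a ~31% decline; at +0.97 C a ~8% decline."""
        m = _meta(0.7, 0.35)
        assert -percent_change_temp(m, 4.32, ANALYTIC_27).percent_change == \
            pytest.approx(31.0, abs=1.5)
        assert -percent_change_temp(m, 0.97, ANALYTIC_27).percent_change == \
            pytest.approx(8.0, abs=1.5)

    def test_co2_decline_at_rcp85(self):
        m = _meta(-0.0197, 0.01, kind="lnrr_co2", attribute="calcification")
        est = percent_change_co2(m, 490.0)
        assert -est.percent_change == pytest.approx(9.2, abs=0.1)

    def test_co2_exponent_scaling_identity(self):
        m = _meta(-0.05, 0.01, kind="lnrr_co2")
        c100 = percent_change_co2(m, 100.0).percent_change
        c63 = percent_change_co2(m, 63.0).percent_change
        assert 1.0 + c63 / 100.0 == pytest.approx(
            (1.0 + c100 / 100.0) ** 0.63, rel=1e-12)

    def test_wrong_kind_raises(self):
        with pytest.raises(TypeError):
            percent_change_temp(_meta(-0.02, 0.01, kind="lnrr_co2"), 1.0,
                                ANALYTIC_27)
        with pytest.raises(TypeError):
            percent_change_co2(_meta(0.7, 0.1), 100.0)

    def test_monotone_in_delta_and_bounded(self):
        m = _meta(0.7, 0.1)
        declines = [-percent_change_temp(m, dt, ANALYTIC_27).percent_change
                    for dt in np.linspace(0.0, 13.0, 25)]
        assert declines == sorted(declines)
        assert all(d < 100.0 for d in declines)

    def test_ci_order_preserved(self):
        m = _meta(0.7, 0.2)
        est = percent_change_temp(m, 3.0, ANALYTIC_27)
        assert est.ci_low <= est.percent_change <= est.ci_high

    def test_inverse_pair_round_trip(self):
        """A noiseless record built with decline d at dT* maps back to d."""
        for true_decline, t0, dt in ((0.31, 27.0, 4.32), (0.08, 24.5, 0.97),
                                     (0.6, 29.0, 7.0)):
            d = delta_inv_kT(t0, t0 + dt)
            rec = ExperimentRecord(
                "s", "g", "survival", "warming",
                10.0, 1.0, 4, 10.0 * (1.0 - true_decline), 1.0, 4,
                t_control_C=t0, t_treatment_C=t0 + dt)
            e = activation_energy(rec)
            m = _meta(e.value, 0.1)
            amap = ArrheniusMap(source="analytic_at_baseline", baseline_T_C=t0)
            est = percent_change_temp(m, dt, amap)
            assert -est.percent_change / 100.0 == pytest.approx(
                true_decline, rel=1e-10)


class TestSensitivityScan:
    def test_exact_rule_significant_effect_hits_first_step(self):
        m = _meta(0.7, 0.1)  # CI well away from zero
        est = min_significant_delta(m, "temperature", step=0.01, cap=13.0,
                                    amap=ANALYTIC_27)
        assert est.min_delta == pytest.approx(0.01)

    def test_exact_rule_nonsignificant_effect_never_hits(self):
        m = _meta(0.1, 0.2)  # CI includes zero
        est = min_significant_delta(m, "temperature", step=0.5, cap=13.0,
                                    amap=ANALYTIC_27)
        assert est.min_delta is None

    def test_rounded_rule_yields_finite_threshold_above_step(self):
        m = _meta(0.7, se=0.3469)  # CI ~ (0.02, 1.38): barely excludes zero
        est = min_significant_delta(m, "temperature", step=0.01, cap=13.0,
                                    precision_rule="rounded", decimals=1,
                                    amap=ANALYTIC_27)
        assert est.min_delta is not None
        assert est.min_delta > 0.01
        # frozen regression value under this rule (scan at 0.01 C steps, CI
        # bounds rounded to one decimal %): the lower decline bound first
        # rounds away from 0.0% at +0.20 C
        assert est.min_delta == pytest.approx(0.20, abs=1e-9)

    def test_co2_scan(self):
        m = _meta(-0.0197, 0.002, kind="lnrr_co2")
        est = min_significant_delta(m, "co2", step=1.0, cap=800.0)
        assert est.min_delta == pytest.approx(1.0)


class TestProjectAll:
    def test_structure_and_gaps(self):
        metas = [_meta(0.7, 0.1, attribute="survival"),
                 _meta(1.5, 0.4, attribute="symbiont_density")]
        scenarios = [
            ScenarioSpec("RCP8.5", "late_century_2081_2100", delta_T_C=4.32),
            ScenarioSpec("RCP8.5", "end_of_century_2091_2100",
                         delta_pco2_uatm=490.0),
        ]
        proj, gaps = project_all(metas, scenarios, ANALYTIC_27)
        assert len(proj) == 2  # two warming metas x one warming scenario
        assert list(gaps["kind"]) == ["lnrr_co2"]

    def test_printed_co2_increments_flow_through(self):
        metas = [_meta(-0.0197, 0.002, kind="lnrr_co2",
                       attribute="calcification")]
        scenarios = [
            ScenarioSpec("RCP2.6", "end_of_century_2091_2100", delta_pco2_uatm=63.0),
            ScenarioSpec("RCP4.5", "end_of_century_2091_2100", delta_pco2_uatm=173.0),
            ScenarioSpec("RCP6.0", "end_of_century_2091_2100", delta_pco2_uatm=276.0),
            ScenarioSpec("RCP8.5", "end_of_century_2091_2100", delta_pco2_uatm=490.0),
        ]
        proj, gaps = project_all(metas, scenarios, ANALYTIC_27)
        assert gaps.empty
        assert list(proj["delta"]) == [63.0, 173.0, 276.0, 490.0]
        # declines strengthen with the increment
        assert proj["percent_change"].is_monotonic_decreasing
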