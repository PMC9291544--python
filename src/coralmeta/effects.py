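"""Per-experiment effect sizes.

Two effect-size currencies are used, one per driver:

* **Arrhenius activation energy** ``E`` (eV) for warming contrasts.  Writing
  the control observation ``V_o`` at absolute temperature ``T_o`` and the
  warming observation ``V_i`` at ``T_i > T_o``,

      E = ln(V_o / V_i) / (1/(k T_o) - 1/(k T_i)),

  with ``k`` the Boltzmann constant in eV/K.  A decline under warming
  (``V_i < V_o``) therefore yields ``E > 0``.  Dividing by the difference in
  inverse thermal energy standardizes contrasts run at different temperature
  increments onto a common per-unit-1/kT scale.

* **Log response ratio per +100 µatm** for CO2 contrasts:

      Ln RR_100 = [ln(x_exp) - ln(x_cont)] / (pCO2_exp - pCO2_cont) * 100,

  so a negative value is a decline per 100 µatm of acidification.

Sampling variances use the standard two-group delta-method log-ratio
variance ``v_ln = SD_t^2/(n_t m_t^2) + SD_c^2/(n_c m_c^2)``, rescaled onto
each effect-size scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from coralmeta.errors import (
    DegenerateContrastError,
    DomainError,
    InsufficientDataError,
)
from coralmeta.records import Arm, ExperimentRecord, FactorialQuad

logger = logging.getLogger(__name__)

#: Boltzmann constant in eV per Kelvin
BOLTZMANN_EV = 8.617e-5

#: exact offset between Celsius and Kelvin
KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class EffectSize:
    """A single effect size with its sampling variance and grouping labels.

    ``kind`` is ``"arrhenius_E"`` (value in eV) or ``"lnrr_co2"`` (value per
    +100 µatm).  ``context`` records whether the contrast was run with the
    other driver at ambient (``single_driver``) or elevated
    (``under_co_stressor``) levels.
    """

    value: float
    variance: float
    kind: str
    context: str
    attribute: str
    study_id: str
    genus: str
    delta_inv_kT: float = math.nan  # eV^-1, arrhenius_E only
    delta_pco2_uatm: float = math.nan  # µatm, lnrr_co2 only
    variance_floored: bool = False


def delta_inv_kT(t_control_C: float, t_treatment_C: float,
                 k: float = BOLTZMANN_EV) -> float:
    """Difference in inverse thermal energy, 1/(k T_o) - 1/(k T_i), in eV^-1.

    Positive whenever the treatment is warmer than the control.
    """
    t_o = t_control_C + KELVIN_OFFSET
    t_i = t_treatment_C + KELVIN_OFFSET
    return 1.0 / (k * t_o) - 1.0 / (k * t_i)


def _log_ratio_variance(control: Arm, treatment: Arm) -> float:
    return (treatment.sd ** 2 / (treatment.n * treatment.mean ** 2)
            + control.sd ** 2 / (control.n * control.mean ** 2))


def _record_arms(rec: ExperimentRecord) -> tuple[Arm, Arm]:
    control = Arm(rec.control_mean, rec.control_sd, rec.control_n)
    treatment = Arm(rec.treatment_mean, rec.treatment_sd, rec.treatment_n)
    return control, treatment


def effect_variance(rec: ExperimentRecord, kind: str,
                    variance_floor: float = 1e-10) -> tuple[float, bool]:
    """Delta-method sampling variance of a record's effect size.

    Returns ``(variance, floored)``; ``floored`` is True when both arm SDs
    are zero and the configurable floor was substituted (the record is then
    effectively noise-free and would otherwise get infinite meta-analytic
    weight).

    Raises
    ------
    InsufficientDataError
        if either arm has n < 2 (a sample SD needs n - 1 >= 1).
    """
    control, treatment = _record_arms(rec)
    if control.n < 2 or treatment.n < 2:
        raise InsufficientDataError(
            f"record {rec.study_id}/{rec.attribute}: variance needs n >= 2 per arm"
        )
    if control.sd < 0 or treatment.sd < 0:
        raise DomainError("negative SD")
    v_ln = _log_ratio_variance(control, treatment)
    if kind == "arrhenius_E":
        d = delta_inv_kT(rec.t_control_C, rec.t_treatment_C)
        if d == 0:
            raise DegenerateContrastError("zero temperature contrast")
        v = v_ln / d ** 2
    elif kind == "lnrr_co2":
        dp = rec.delta_pco2_uatm
        if not dp > 0:
            raise DegenerateContrastError("zero pCO2 contrast")
        v = v_ln * (100.0 / dp) ** 2
    else:
        raise ValueError(f"unknown effect-size kind {kind!r}")
    if v == 0:
        logger.warning("record %s/%s: both SDs zero, applying variance floor %g",
                       rec.study_id, rec.attribute, variance_floor)
        return variance_floor, True
    return v, False


def activation_energy(rec: ExperimentRecord,
                      variance_floor: float = 1e-10) -> EffectSize:
    """Arrhenius activation energy E (eV) of a warming contrast.

    The sign convention follows the ratio orientation control/treatment: a
    decline under warming gives E > 0.  Swapping the arm labels negates both
    the log ratio and the inverse-thermal-energy difference, leaving E
    unchanged.
    """
    if rec.arm_type not in ("warming", "both"):
        raise DomainError(f"arm_type {rec.arm_type!r} has no warming contrast")
    if not (rec.control_mean > 0 and rec.treatment_mean > 0):
        raise DomainError("activation energy requires strictly positive means")
    d = delta_inv_kT(rec.t_control_C, rec.t_treatment_C)
    if d == 0 or math.isnan(d):
        raise DegenerateContrastError("temperature contrast is zero or undefined")
    value = math.log(rec.control_mean / rec.treatment_mean) / d
    variance, floored = effect_variance(rec, "arrhenius_E", variance_floor)
    under_oa = rec.arm_type == "both" or rec.co_stressor
    return EffectSize(
        value=value,
        variance=variance,
        kind="arrhenius_E",
        context="under_co_stressor" if under_oa else "single_driver",
        attribute=rec.attribute,
        study_id=rec.study_id,
        genus=rec.genus,
        delta_inv_kT=d,
        variance_floored=floored,
    )


def lnrr_co2(rec: ExperimentRecord, variance_floor: float = 1e-10) -> EffectSize:
    """Log response ratio per +100 µatm pCO2 of a CO2 contrast."""
    if rec.arm_type not in ("co2", "both"):
        raise DomainError(f"arm_type {rec.arm_type!r} has no CO2 contrast")
    if not (rec.control_mean > 0 and rec.treatment_mean > 0):
        raise DomainError("log response ratio requires strictly positive means")
    dp = rec.delta_pco2_uatm
    if not dp > 0 or math.isnan(dp):
        raise DegenerateContrastError("pCO2 contrast is zero or undefined")
    value = (math.log(rec.treatment_mean) - math.log(rec.control_mean)) / dp * 100.0
    variance, floored = effect_variance(rec, "lnrr_co2", variance_floor)
    under_warming = rec.arm_type == "both" or rec.co_stressor
    return EffectSize(
        value=value,
        variance=variance,
        kind="lnrr_co2",
        context="under_co_stressor" if under_warming else "single_driver",
        attribute=rec.attribute,
        study_id=rec.study_id,
        genus=rec.genus,
        delta_pco2_uatm=dp,
        variance_floored=floored,
    )


def quad_to_records(q: FactorialQuad) -> list[ExperimentRecord]:
    """Decompose a factorial quad into the four informative two-arm contrasts.

    * warming vs control                      -> warming effect, single driver
    * co2 vs control                          -> CO2 effect, single driver
    * both vs co2 (warming at elevated pCO2)  -> warming effect under OA
    * both vs warming (CO2 at elevated T)     -> CO2 effect under warming

    The under-co-stressor contrasts vary only one driver, so they carry
    ``arm_type`` of that driver plus the ``co_stressor`` flag.
    """
    base = dict(study_id=q.study_id, genus=q.genus, species=q.species,
                attribute=q.attribute, quad_id=q.quad_id)

    def rec(control: Arm, treatment: Arm, arm_type: str, co_stressor=False, **drivers):
        return ExperimentRecord(
            arm_type=arm_type, co_stressor=co_stressor,
            control_mean=control.mean, control_sd=control.sd, control_n=control.n,
            treatment_mean=treatment.mean, treatment_sd=treatment.sd,
            treatment_n=treatment.n, **base, **drivers,
        )

    return [
        rec(q.control, q.warming, "warming",
            t_control_C=q.t_control_C, t_treatment_C=q.t_treatment_C),
        rec(q.control, q.co2, "co2",
            pco2_control_uatm=q.pco2_control_uatm,
            pco2_treatment_uatm=q.pco2_treatment_uatm),
        rec(q.co2, q.both, "warming", co_stressor=True,
            t_control_C=q.t_control_C, t_treatment_C=q.t_treatment_C,
            pco2_control_uatm=q.pco2_treatment_uatm,
            pco2_treatment_uatm=q.pco2_treatment_uatm),
        rec(q.warming, q.both, "co2", co_stressor=True,
            t_control_C=q.t_treatment_C, t_treatment_C=q.t_treatment_C,
            pco2_control_uatm=q.pco2_control_uatm,
            pco2_treatment_uatm=q.pco2_treatment_uatm),
    ]


def compute_effect_sizes(
    records: Iterable[ExperimentRecord],
    quads: Iterable[FactorialQuad] = (),
    variance_floor: float = 1e-10,
) -> pd.DataFrame:
    """Tidy effect-size table: one row per record per applicable kind.

    Warming records yield an ``arrhenius_E`` row; CO2 records an ``lnrr_co2``
    row.  ``both`` records (control vs combined treatment) are ambiguous
    between drivers and are skipped here with a log message — factorial quads
    should instead be passed via ``quads``, whose within-level contrasts
    (both vs co2 for warming under OA; both vs warming for CO2 under
    warming) cleanly separate the drivers.
    """
    rows = []

    def emit(rec, fn):
        try:
            es = fn(rec, variance_floor=variance_floor)
        except (DomainError, DegenerateContrastError, InsufficientDataError) as exc:
            logger.warning("skipping %s/%s: %s", rec.study_id, rec.attribute, exc)
            return
        rows.append(es)

    for rec in records:
        if rec.arm_type == "warming":
            emit(rec, activation_energy)
        elif rec.arm_type == "co2":
            emit(rec, lnrr_co2)
        else:
            logger.info("record %s: combined-arm contrast skipped in tidy table",
                        rec.study_id)
    for q in quads:
        w_single, c_single, w_oa, c_warm = quad_to_records(q)
        emit(w_single, activation_energy)
        emit(c_single, lnrr_co2)
        emit(w_oa, activation_energy)
        emit(c_warm, lnrr_co2)

    cols = ["value", "variance", "kind", "context", "attribute", "study_id",
            "genus", "delta_inv_kT", "delta_pco2_uatm", "variance_floored"]
    return pd.DataFrame([{c: getattr(es, c) for c in cols} for es in rows],
                        columns=cols)
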