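"""Back-transformation of pooled effect sizes to scenario percent changes.

A pooled activation energy E (eV) converts to an expected percent change at
a temperature increase dT through the inverse-thermal-energy increment
``d = Delta(1/kT)``:

    percent_change = 100 * (exp(-E * d) - 1),

so a positive E (decline under warming) gives a negative percent change.
The mapping dT -> Delta(1/kT) is either fitted by ordinary least squares on
the dataset's own (dT, Delta(1/kT)) pairs, or evaluated analytically at a
configured baseline temperature Tb:

    d(dT) = 1/(k Tb) - 1/(k (Tb + dT)),  Tb in Kelvin.

A pooled CO2 log response ratio per +100 µatm converts at a pCO2 increase
dP as ``percent_change = 100 * (exp(lnrr * dP / 100) - 1)``.

Sign convention throughout: **negative percent change = decline** (the
orientation used when changes are plotted against zero).  Use
``percent_decline`` for the positive-decline presentation of results prose.
CI bounds back-transform the Wald bounds of the pooled effect; the
exponential is monotone, so bound order is preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from coralmeta.effects import BOLTZMANN_EV, delta_inv_kT
from coralmeta.errors import DomainError
from coralmeta.meta import MetaResult
from coralmeta.records import ExperimentRecord, ScenarioSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArrheniusMap:
    """Mapping from a warming increment (°C) to Delta(1/kT) (eV^-1).

    ``fitted_from_data`` maps are the OLS line through the dataset's own
    (dT, Delta(1/kT)) pairs; ``analytic_at_baseline`` maps evaluate the
    exact expression at ``baseline_T_C``.
    """

    source: str
    slope: float = math.nan
    intercept: float = math.nan
    baseline_T_C: float = math.nan
    k: float = BOLTZMANN_EV

    def delta(self, delta_T_C: float) -> float:
        """Delta(1/kT) in eV^-1 for a warming of ``delta_T_C`` degrees."""
        if self.source == "analytic_at_baseline":
            return delta_inv_kT(self.baseline_T_C, self.baseline_T_C + delta_T_C,
                                k=self.k)
        return self.slope * delta_T_C + self.intercept


@dataclass(frozen=True)
class ProjectionEstimate:
    """Expected percent change of one attribute under one scenario.

    ``percent_change`` is signed: negative = decline.  ``percent_decline``
    gives the same number with declines positive, as results are usually
    quoted.
    """

    attribute: str
    percent_change: float
    ci_low: float
    ci_high: float
    significant: bool
    context: str = ""
    kind: str = ""
    rcp: str = ""
    period: str = ""
    delta: float = math.nan

    @property
    def percent_decline(self) -> float:
        return -self.percent_change


@dataclass(frozen=True)
class SensitivityEstimate:
    """Smallest driver increment producing a significant percent change."""

    attribute: str
    driver: str
    min_delta: float | None
    percent_change_at_min: float
    precision_rule: str
    context: str = ""


def fit_arrhenius_map(
    records: Iterable[ExperimentRecord] = (),
    baseline_temperature_C: float = 27.0,
    k: float = BOLTZMANN_EV,
) -> ArrheniusMap:
    """OLS fit of Delta(1/kT) on dT across warming records.

    Falls back to the analytic map at ``baseline_temperature_C`` when no
    warming records are supplied.  Note the exact relation at fixed control
    temperature is mildly concave in dT, so the fitted line is a least-squares
    linearization over the dataset's dT range, not an exact reproduction.
    """
    pairs = [
        (rec.delta_T_C, delta_inv_kT(rec.t_control_C, rec.t_treatment_C, k=k))
        for rec in records
        if rec.arm_type in ("warming", "both") and rec.delta_T_C > 0
    ]
    if len(pairs) < 2:
        if pairs:
            logger.warning("only %d warming record(s): falling back to the "
                           "analytic map at %.2f C", len(pairs),
                           baseline_temperature_C)
        return ArrheniusMap(source="analytic_at_baseline",
                            baseline_T_C=baseline_temperature_C, k=k)
    x = np.array([p[0] for p in pairs])
    yv = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise DomainError("all warming increments identical: singular fit")
    slope, intercept = np.polyfit(x, yv, 1)
    if slope <= 0:
        raise DomainError("fitted map has non-positive slope")
    return ArrheniusMap(source="fitted_from_data", slope=float(slope),
                        intercept=float(intercept), k=k)


def _back_transform(x: float) -> float:
    """Percent change corresponding to a log-scale change x."""
    return 100.0 * (math.exp(x) - 1.0)


def percent_change_temp(meta: MetaResult, delta_T_C: float,
                        amap: ArrheniusMap) -> ProjectionEstimate:
    """Expected percent change under a warming of ``delta_T_C`` degrees."""
    if meta.kind not in ("", "arrhenius_E"):
        raise TypeError(f"expected an arrhenius_E pooled effect, got {meta.kind!r}")
    if delta_T_C < 0:
        raise DomainError("warming increment must be >= 0")
    d = amap.delta(delta_T_C)
    pc = _back_transform(-meta.estimate * d)
    lo = _back_transform(-meta.ci_high * d)  # larger E -> larger decline
    hi = _back_transform(-meta.ci_low * d)
    significant = not (lo <= 0.0 <= hi)
    return ProjectionEstimate(
        attribute=meta.attribute, percent_change=pc, ci_low=lo, ci_high=hi,
        significant=significant, context=meta.context, kind="arrhenius_E",
        delta=delta_T_C,
    )


def percent_change_co2(meta: MetaResult, delta_pco2_uatm: float) -> ProjectionEstimate:
    """Expected percent change under a pCO2 increase of ``delta_pco2_uatm``."""
    if meta.kind not in ("", "lnrr_co2"):
        raise TypeError(f"expected an lnrr_co2 pooled effect, got {meta.kind!r}")
    if delta_pco2_uatm < 0:
        raise DomainError("pCO2 increment must be >= 0")
    scale = delta_pco2_uatm / 100.0
    pc = _back_transform(meta.estimate * scale)
    lo = _back_transform(meta.ci_low * scale)
    hi = _back_transform(meta.ci_high * scale)
    significant = not (lo <= 0.0 <= hi)
    return ProjectionEstimate(
        attribute=meta.attribute, percent_change=pc, ci_low=lo, ci_high=hi,
        significant=significant, context=meta.context, kind="lnrr_co2",
        delta=delta_pco2_uatm,
    )


def min_significant_delta(
    meta: MetaResult,
    driver: str,
    step: float,
    cap: float,
    precision_rule: str = "exact",
    decimals: int = 1,
    amap: ArrheniusMap | None = None,
) -> SensitivityEstimate:
    """Scan driver increments (step, 2*step, ...) up to ``cap`` for the first
    significant back-transformed percent change.

    ``precision_rule="exact"`` requires the CI to strictly exclude zero; as
    the back-transform is monotone this is either the first scanned value or
    never.  ``"rounded"`` requires exclusion after rounding both CI bounds to
    ``decimals`` decimal places (a bound that rounds to 0.0 still counts as
    touching zero), which yields finite, reporting-precision-dependent
    thresholds even for effects whose CI already excludes zero.

    ``min_delta`` is None when no increment up to the cap qualifies.
    """
    if step <= 0:
        raise DomainError("step must be > 0")
    if not math.isfinite(cap):
        raise DomainError("cap must be finite")
    if precision_rule not in ("exact", "rounded"):
        raise ValueError(f"unknown precision_rule {precision_rule!r}")
    if driver == "temperature":
        if amap is None:
            raise DomainError("temperature scan needs an ArrheniusMap")
        project = lambda d: percent_change_temp(meta, d, amap)
    elif driver == "co2":
        project = lambda d: percent_change_co2(meta, d)
    else:
        raise ValueError(f"unknown driver {driver!r}")

    n_steps = int(math.floor(cap / step + 1e-9))
    for i in range(1, n_steps + 1):
        delta = i * step
        est = project(delta)
        if precision_rule == "exact":
            hit = est.significant
        else:
            lo = round(est.ci_low, decimals)
            hi = round(est.ci_high, decimals)
            hit = not (lo <= 0.0 <= hi)
        if hit:
            return SensitivityEstimate(
                attribute=meta.attribute, driver=driver, min_delta=delta,
                percent_change_at_min=est.percent_change,
                precision_rule=precision_rule, context=meta.context,
            )
    return SensitivityEstimate(
        attribute=meta.attribute, driver=driver, min_delta=None,
        percent_change_at_min=math.nan, precision_rule=precision_rule,
        context=meta.context,
    )


def project_all(
    meta_results: Iterable[MetaResult],
    scenarios: Sequence[ScenarioSpec],
    amap: ArrheniusMap,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project every pooled effect under every applicable scenario.

    Warming scenarios (delta_T_C > 0) apply to ``arrhenius_E`` pooled
    effects; CO2 scenarios (delta_pco2_uatm > 0) to ``lnrr_co2`` effects.
    Returns ``(projections, gaps)`` where gaps lists scenario/kind
    combinations with no matching pooled effect.
    """
    meta_results = list(meta_results)
    rows = []
    gaps = []
    for sc in scenarios:
        for kind, delta, fn in (
            ("arrhenius_E", sc.delta_T_C,
             lambda m, d: percent_change_temp(m, d, amap)),
            ("lnrr_co2", sc.delta_pco2_uatm, percent_change_co2),
        ):
            if delta <= 0:
                continue
            matches = [m for m in meta_results if m.kind == kind]
            if not matches:
                gaps.append({"rcp": sc.rcp, "period": sc.period, "kind": kind,
                             "reason": "no pooled effect of this kind"})
                continue
            for m in matches:
                est = fn(m, delta)
                rows.append({
                    "attribute": m.attribute, "kind": kind, "context": m.context,
                    "rcp": sc.rcp, "period": sc.period, "delta": delta,
                    "percent_change": est.percent_change,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "significant": est.significant,
                })
    proj_cols = ["attribute", "kind", "context", "rcp", "period", "delta",
                 "percent_change", "ci_low", "ci_high", "significant"]
    return (pd.DataFrame(rows, columns=proj_cols),
            pd.DataFrame(gaps, columns=["rcp", "period", "kind", "reason"]))
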