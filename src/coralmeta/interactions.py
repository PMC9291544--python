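"""Factorial warming x CO2 interaction effect sizes and classification.

A full-factorial experiment has four arms — control, warming only, CO2 only,
and both stressors.  Because both effect-size currencies used elsewhere in
the pipeline are multiplicative (log-ratio based), the natural null for the
combined arm is the multiplicative null ``x_Both = x_W * x_C / x_Cont``.  The
standardized interaction strength is

    LnRR_Inter = [ln x_Both - ln x_W - ln x_C + ln x_Cont] / (2 s),

with ``s`` the four-arm pooled standard deviation.  Individual effects are
standardized the same way: ``LnRR_W = (ln x_W - ln x_Cont)/s`` and
``LnRR_C = (ln x_C - ln x_Cont)/s``.  A multiplicative-null quad has
interaction strength exactly zero.

Two sampling-variance modes are available:

* ``"printed"`` (default) — the conventional factorial-meta-analysis form
  ``1/n_W + 1/n_C + 1/n_B + 1/n_Cont + LnRR_Inter^2 / (2 * sum(n))`` with a
  fixed z = 1.96 CI.  Its leading terms are not scaled by ``s``, so on data
  whose arm SDs are small relative to the means it is deliberately
  conservative (wide CIs, interactions rarely leave the additive class).
* ``"delta"`` — a calibrated delta-method variance of the standardized
  log-ratio contrast, ``[sum_i SD_i^2/(n_i m_i^2)]/(4 s^2)``, with a
  Student-t critical value at the pooled degrees of freedom
  ``sum(n_i) - 4`` (the df behind the pooled SD itself).  Use this mode when
  the CI is meant to attain nominal coverage (e.g. type-I calibration
  studies).

Classification: **additive** when the CI contains zero.  Otherwise, when the
individual effects are both negative or of mixed sign, a negative
interaction is **synergistic** (the combination is worse than the
multiplicative expectation) and a positive one **antagonistic**.  When both
individual effects are positive the interpretation inverts (a positive
interaction then means the combination overshoots, i.e. synergism); such
results carry a ``sign_inverted`` flag rather than being silently folded in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

from coralmeta.errors import DomainError
from coralmeta.records import FactorialQuad

CLASSES = ("additive", "synergistic", "antagonistic")


@dataclass(frozen=True)
class InteractionResult:
    """Interaction strength for one factorial quad, with CI and class."""

    lnrr_inter: float
    variance: float
    ci_low: float
    ci_high: float
    lnrr_warming: float
    lnrr_pco2: float
    pooled_sd: float
    classification: str
    sign_inverted: bool
    variance_mode: str
    study_id: str = ""
    genus: str = ""
    attribute: str = ""


def pooled_sd(q: FactorialQuad) -> float:
    """Four-arm pooled standard deviation."""
    arms = q.arms().values()
    num = sum((a.n - 1) * a.sd ** 2 for a in arms)
    den = sum(a.n for a in arms) - 4
    if den <= 0:
        raise DomainError("pooled SD needs n >= 2 in every arm")
    return math.sqrt(num / den)


def classify(lnrr_inter: float, ci_low: float, ci_high: float,
             lnrr_warming: float, lnrr_pco2: float) -> tuple[str, bool]:
    """Classify an interaction; returns (class, sign_inverted flag)."""
    if ci_low <= 0.0 <= ci_high:
        return "additive", False
    both_positive = lnrr_warming > 0 and lnrr_pco2 > 0
    if both_positive:
        # inverted convention: overshoot above the multiplicative
        # expectation of two beneficial effects is synergism
        cls = "synergistic" if lnrr_inter > 0 else "antagonistic"
        return cls, True
    cls = "synergistic" if lnrr_inter < 0 else "antagonistic"
    return cls, False


def interaction_effect(q: FactorialQuad,
                       variance_mode: str = "printed") -> InteractionResult:
    """Standardized interaction strength, CI and classification for a quad."""
    problems = q.validate()
    if problems:
        raise DomainError("; ".join(problems))
    if variance_mode not in ("printed", "delta"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    s = pooled_sd(q)
    if s == 0:
        raise DomainError(
            "pooled SD is zero (all arm SDs zero): standardized interaction "
            "strength is undefined for noise-free arms"
        )
    a = q.arms()
    lb, lw, lc, l0 = (math.log(a[k].mean) for k in ("both", "warming", "co2", "control"))
    inter = (lb - lw - lc + l0) / (2.0 * s)
    ind_w = (lw - l0) / s
    ind_c = (lc - l0) / s

    n_sum = sum(arm.n for arm in a.values())
    if variance_mode == "printed":
        variance = (sum(1.0 / arm.n for arm in a.values())
                    + inter ** 2 / (2.0 * n_sum))
        crit = 1.96
    else:
        v_log = sum(arm.sd ** 2 / (arm.n * arm.mean ** 2) for arm in a.values())
        variance = v_log / (4.0 * s ** 2)
        crit = float(stats.t.ppf(0.975, n_sum - 4))
    half = crit * math.sqrt(variance)
    ci_low, ci_high = inter - half, inter + half
    cls, inverted = classify(inter, ci_low, ci_high, ind_w, ind_c)
    return InteractionResult(
        lnrr_inter=inter, variance=variance, ci_low=ci_low, ci_high=ci_high,
        lnrr_warming=ind_w, lnrr_pco2=ind_c, pooled_sd=s,
        classification=cls, sign_inverted=inverted, variance_mode=variance_mode,
        study_id=q.study_id, genus=q.genus, attribute=q.attribute,
    )


def interaction_summary(results: Iterable[InteractionResult]) -> Mapping[str, object]:
    """Counts and proportions per interaction class (empty classes reported as 0)."""
    results = list(results)
    if not results:
        raise DomainError("interaction summary needs at least one result")
    counts = {c: 0 for c in CLASSES}
    for r in results:
        counts[r.classification] += 1
    total = len(results)
    return {
        "counts": counts,
        "proportions": {c: counts[c] / total for c in CLASSES},
        "n": total,
    }
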