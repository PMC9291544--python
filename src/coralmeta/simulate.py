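"""Synthetic-data generators with known ground truth.

Three generators cover every input the pipeline consumes:

* :func:`gen_experiments` — two-arm warming and CO2 contrasts whose latent
  treatment/control ratio follows an exact Arrhenius decline with a chosen
  true activation energy (or an exact log-ratio CO2 response), plus
  normally-distributed between-study and between-genus heterogeneity on the
  effect-size scale and lognormal replicate noise within arms.
* :func:`gen_factorial` — full-factorial quads built around the
  multiplicative null, with a chosen interaction magnitude on the log scale
  (0 = additive truth).
* :func:`gen_sst` — daily SST series with sinusoidal seasonality, AR(1)
  noise, a post-baseline linear trend, and injected heatwave blocks, on a
  365-day (no leap day) calendar.

Every draw flows from a single integer seed, and each generator returns a
truth table recording the latent values needed to compute downstream
expectations without re-running the generator.  Design ranges default to
the envelopes of the experimental literature the pipeline emulates: control
temperatures 24–30 °C, warming increments +0.5 to +13 °C, control pCO2
297–486 µatm and increments +100 to +800 µatm.

Lognormal replicate noise keeps outcomes strictly positive, which the
log-ratio effect sizes require; the lognormal is parameterized by its
arithmetic mean and coefficient of variation, so reported arm means are
unbiased for the latent means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from coralmeta.effects import delta_inv_kT
from coralmeta.mhw import SSTSeries
from coralmeta.records import Arm, ExperimentRecord, FactorialQuad


@dataclass
class ExperimentSimSpec:
    """Study conditions for the experiment-record generator.

    ``noise_cv`` is the within-arm lognormal coefficient of variation;
    ``between_study_sd`` / ``between_genus_sd`` are heterogeneity SDs on the
    effect-size scale (eV for warming, per-100-µatm log ratio for CO2).
    """

    true_E_by_attribute: dict[str, float] = field(
        default_factory=lambda: {"survival": 0.7, "symbiont_density": 1.5})
    true_lnrr100_by_attribute: dict[str, float] = field(
        default_factory=lambda: {"calcification": -0.0197})
    n_studies: int = 40
    effects_per_study: int = 2
    n_genera: int = 10
    control_T_range: tuple[float, float] = (24.0, 30.0)
    warming_range: tuple[float, float] = (0.5, 13.0)
    control_pco2_range: tuple[float, float] = (297.0, 486.0)
    delta_pco2_range: tuple[float, float] = (100.0, 800.0)
    control_mean_range: tuple[float, float] = (5.0, 50.0)
    noise_cv: float = 0.15
    arm_n_range: tuple[int, int] = (4, 10)
    between_study_sd: float = 0.0
    between_genus_sd: float = 0.0
    seed: int = 0


@dataclass
class SSTSimSpec:
    """Study conditions for the daily-SST generator.

    ``injected_events`` holds (start, duration_days, amplitude_C) triples;
    ``start`` is a day offset from the first day of the series.  The linear
    trend is zero throughout the baseline segment and ramps afterwards.
    """

    years: int = 30
    baseline_years: int = 10
    start_year: int = 1861
    mean_C: float = 27.0
    seasonal_amplitude_C: float = 0.0
    ar1_coeff: float = 0.0
    noise_sd_C: float = 0.0
    trend_C_per_decade: float = 0.0
    injected_events: Sequence[tuple[int, int, float]] = ()
    truth_percentile: float = 90.0
    seed: int = 0


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + cv ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _sample_arm(rng: np.random.Generator, mean: float, cv: float, n: int,
                sampling: bool) -> Arm:
    if cv == 0.0 or not sampling:
        return Arm(mean=mean, sd=cv * mean, n=n)
    mu, sigma = _lognormal_params(mean, cv)
    draws = rng.lognormal(mu, sigma, size=n)
    return Arm(mean=float(draws.mean()), sd=float(draws.std(ddof=1)), n=n)


def gen_experiments(
    spec: ExperimentSimSpec,
    sampling: bool = True,
) -> tuple[list[ExperimentRecord], pd.DataFrame]:
    """Generate two-arm warming and CO2 records with a truth table.

    Per record the latent effect is the attribute's true value plus the
    study's and genus's random deviations; the latent treatment mean is
    ``control * exp(-E_latent * Delta(1/kT))`` for warming records and
    ``control * exp(lnrr_latent * dpCO2 / 100)`` for CO2 records.  With
    ``sampling=True`` each arm reports the sample mean and SD of ``n``
    lognormal replicates; with ``sampling=False`` arms report the exact
    latent means with population SDs (``noise_cv * mean``), which makes the
    record-level effect size recover the latent effect exactly.
    """
    rng = np.random.default_rng(spec.seed)
    genera = [f"genus_{g:02d}" for g in range(spec.n_genera)]
    genus_dev = {g: rng.normal(0.0, spec.between_genus_sd) if spec.between_genus_sd
                 else 0.0 for g in genera}

    kinds = ([("arrhenius_E", a, t) for a, t in spec.true_E_by_attribute.items()]
             + [("lnrr_co2", a, t) for a, t in spec.true_lnrr100_by_attribute.items()])
    if not kinds:
        raise ValueError("spec defines no true effects")

    records: list[ExperimentRecord] = []
    truth_rows = []
    for s in range(spec.n_studies):
        study_id = f"study_{s:03d}"
        genus = genera[int(rng.integers(0, spec.n_genera))]
        u_study = rng.normal(0.0, spec.between_study_sd) if spec.between_study_sd else 0.0
        for e in range(spec.effects_per_study):
            kind, attribute, true_val = kinds[int(rng.integers(0, len(kinds)))]
            latent = true_val + u_study + genus_dev[genus]
            m0 = float(rng.uniform(*spec.control_mean_range))
            n_c = int(rng.integers(spec.arm_n_range[0], spec.arm_n_range[1] + 1))
            n_t = int(rng.integers(spec.arm_n_range[0], spec.arm_n_range[1] + 1))
            if kind == "arrhenius_E":
                t0 = float(rng.uniform(*spec.control_T_range))
                dt = float(rng.uniform(*spec.warming_range))
                d = delta_inv_kT(t0, t0 + dt)
                m1 = m0 * math.exp(-latent * d)
                drivers = dict(t_control_C=t0, t_treatment_C=t0 + dt)
                delta = dt
            else:
                p0 = float(rng.uniform(*spec.control_pco2_range))
                dp = float(rng.uniform(*spec.delta_pco2_range))
                m1 = m0 * math.exp(latent * dp / 100.0)
                drivers = dict(pco2_control_uatm=p0, pco2_treatment_uatm=p0 + dp)
                delta = dp
            control = _sample_arm(rng, m0, spec.noise_cv, n_c, sampling)
            treatment = _sample_arm(rng, m1, spec.noise_cv, n_t, sampling)
            records.append(ExperimentRecord(
                study_id=study_id, genus=genus, attribute=attribute,
                arm_type="warming" if kind == "arrhenius_E" else "co2",
                control_mean=control.mean, control_sd=control.sd, control_n=n_c,
                treatment_mean=treatment.mean, treatment_sd=treatment.sd,
                treatment_n=n_t, **drivers,
            ))
            truth_rows.append({
                "study_id": study_id, "genus": genus, "attribute": attribute,
                "kind": kind, "true_value": true_val, "latent_value": latent,
                "u_study": u_study, "w_genus": genus_dev[genus],
                "delta": delta, "control_latent_mean": m0,
                "treatment_latent_mean": m1,
            })
    return records, pd.DataFrame(truth_rows)


def gen_factorial(
    spec: ExperimentSimSpec,
    interaction_magnitude: float = 0.0,
    n_quads: int = 100,
    attribute: str = "calcification",
    sampling: bool = True,
    seed: int | None = None,
) -> tuple[list[FactorialQuad], pd.DataFrame]:
    """Generate full-factorial quads around the multiplicative null.

    The both-stressor arm's latent mean is the multiplicative-null value
    ``control * (warming/control) * (co2/control)`` times
    ``exp(interaction_magnitude)``; magnitude 0 is an additive truth.
    Individual warming and CO2 effects follow the spec's true effect sizes
    for ``attribute`` when present (falling back to mild declines).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    true_E = spec.true_E_by_attribute.get(attribute, 0.5)
    true_lnrr = spec.true_lnrr100_by_attribute.get(attribute, -0.01)

    quads: list[FactorialQuad] = []
    truth_rows = []
    for q in range(n_quads):
        m0 = float(rng.uniform(*spec.control_mean_range))
        t0 = float(rng.uniform(*spec.control_T_range))
        dt = float(rng.uniform(*spec.warming_range))
        p0 = float(rng.uniform(*spec.control_pco2_range))
        dp = float(rng.uniform(*spec.delta_pco2_range))
        mw = m0 * math.exp(-true_E * delta_inv_kT(t0, t0 + dt))
        mc = m0 * math.exp(true_lnrr * dp / 100.0)
        mb = mw * mc / m0 * math.exp(interaction_magnitude)
        ns = [int(rng.integers(max(2, spec.arm_n_range[0]),
                               spec.arm_n_range[1] + 1)) for _ in range(4)]
        arms = {
            name: _sample_arm(rng, mean, spec.noise_cv, n, sampling)
            for (name, mean), n in zip(
                [("control", m0), ("warming", mw), ("co2", mc), ("both", mb)], ns)
        }
        quads.append(FactorialQuad(
            study_id=f"fstudy_{q:03d}", genus=f"genus_{q % spec.n_genera:02d}",
            attribute=attribute, quad_id=f"quad_{q:03d}",
            control=arms["control"], warming=arms["warming"],
            co2=arms["co2"], both=arms["both"],
            t_control_C=t0, t_treatment_C=t0 + dt,
            pco2_control_uatm=p0, pco2_treatment_uatm=p0 + dp,
        ))
        truth_rows.append({
            "quad_id": f"quad_{q:03d}", "interaction_magnitude": interaction_magnitude,
            "control_latent_mean": m0, "warming_latent_mean": mw,
            "co2_latent_mean": mc, "both_latent_mean": mb,
            "delta_T_C": dt, "delta_pco2_uatm": dp,
        })
    return quads, pd.DataFrame(truth_rows)


def _noleap_dates(start_year: int, years: int) -> pd.DatetimeIndex:
    days = pd.date_range(f"{start_year}-01-01", f"{start_year + years - 1}-12-31",
                         freq="D")
    return days[~((days.month == 2) & (days.day == 29))]


def gen_sst(spec: SSTSimSpec) -> tuple[SSTSeries, pd.DataFrame]:
    """Generate a daily SST series plus a truth table of injected events.

    The series is mean + seasonality + AR(1) noise + a linear trend that
    starts at zero at the end of the baseline segment, with each injected
    block added on top.  The truth table records, per injected event, the
    analytic (noise-free) expectation of its exceedance day count and maximum
    intensity over the noise-free ``truth_percentile`` threshold — exact for
    noiseless specs, approximate otherwise.
    """
    if not 0.0 <= spec.ar1_coeff < 1.0:
        raise ValueError("ar1_coeff must lie in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    dates = _noleap_dates(spec.start_year, spec.years)
    n = len(dates)
    # use position within year for a clean 365-day seasonal phase (day-of-year
    # would carry post-Feb-28 offsets in leap years of the no-leap calendar)
    year = dates.year.to_numpy()
    pos = np.concatenate([np.arange((year == y).sum()) for y in np.unique(year)])
    season = spec.seasonal_amplitude_C * np.sin(2.0 * math.pi * pos / 365.0)

    baseline_days = spec.baseline_years * 365
    elapsed_years = (np.arange(n) - baseline_days) / 365.0
    trend = spec.trend_C_per_decade * np.clip(elapsed_years, 0.0, None) / 10.0

    clean = spec.mean_C + season + trend
    for start, duration, amplitude in spec.injected_events:
        clean[start:start + duration] += amplitude

    if spec.noise_sd_C > 0:
        innov_sd = spec.noise_sd_C * math.sqrt(1.0 - spec.ar1_coeff ** 2)
        eps = rng.normal(0.0, innov_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, spec.noise_sd_C)
        for t in range(1, n):
            noise[t] = spec.ar1_coeff * noise[t - 1] + eps[t]
    else:
        noise = np.zeros(n)

    sst = clean + noise
    baseline_span = (dates[0], dates[baseline_days - 1])
    series = SSTSeries(dates=dates, sst=sst, baseline_span=baseline_span,
                      model_id=f"sim_{spec.seed}")

    base_mask = np.arange(n) < baseline_days
    thr = float(np.percentile(clean[base_mask], spec.truth_percentile,
                              method="linear"))
    truth_rows = []
    for start, duration, amplitude in spec.injected_events:
        block = clean[start:start + duration]
        above = block > thr
        truth_rows.append({
            "start_index": start,
            "start_date": dates[start],
            "duration_days": duration,
            "amplitude_C": amplitude,
            "expected_exceedance_days": int(above.sum()),
            "expected_max_intensity_C":
                float((block - thr).max()) if above.any() else math.nan,
            "noise_free_threshold_C": thr,
        })
    truth_cols = ["start_index", "start_date", "duration_days", "amplitude_C",
                  "expected_exceedance_days", "expected_max_intensity_C",
                  "noise_free_threshold_C"]
    return series, pd.DataFrame(truth_rows, columns=truth_cols)
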