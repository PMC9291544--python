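# Methods

`coralmeta` projects how coral holobiont performance responds to
intensifying marine heatwaves (MHWs) and ocean acidification (OA), by
pooling experiment-level contrasts into standardized effect sizes,
meta-analysing them with crossed random factors, and back-transforming the
pooled effects into expected per cent changes under emissions-scenario
increments. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data studies do and do not show.

## Effect sizes

**Warming.** Each warming contrast (control observation `V_o` at absolute
temperature `T_o`, treatment `V_i` at `T_i > T_o`) is converted to an
Arrhenius activation energy

    E = ln(V_o / V_i) / (1/(k·T_o) − 1/(k·T_i))      [eV],

with `k = 8.617e-5` eV/K and Kelvin = Celsius + 273.15 exactly. Dividing by
the inverse-thermal-energy difference standardizes experiments run at
different warming increments onto a common per-unit-1/kT scale; under the
package's orientation a decline under warming gives `E > 0`. The estimator
is exact for any single contrast generated by an Arrhenius decline — no
regression over multiple temperatures is needed.

**CO2.** Each acidification contrast becomes a log response ratio per
+100 µatm:

    LnRR₁₀₀ = [ln(x̄_exp) − ln(x̄_cont)] / ΔpCO2 × 100,

negative for declines. Both effect sizes are undefined for non-positive
means; such records are excluded with a row-level report (an optional
continuity correction for zero-survival outcomes is deliberately not
applied by default, since whether one is appropriate depends on how the
survival proportions were measured).

**Sampling variances** use the standard two-group delta-method log-ratio
form `v_ln = SD_t²/(n_t·m_t²) + SD_c²/(n_c·m_c²)`, rescaled by `1/Δ(1/kT)²`
or `(100/ΔpCO2)²`. The weighted meta-analysis requires a variance for every
record; when both arm SDs are zero (noise-free synthetic records) a
configurable floor (default 1e-10) is substituted and flagged rather than
granting infinite weight. Records need `n ≥ 2` per arm.

## Factorial interactions

Full-factorial experiments (control / warming / CO2 / both) are scored by
the standardized interaction strength

    LnRR_Inter = [ln x̄_B − ln x̄_W − ln x̄_C + ln x̄_Cont] / (2s),

with `s` the four-arm pooled SD. The grouping is fixed so that a
multiplicative null (`x̄_B = x̄_W · x̄_C / x̄_Cont`) gives exactly zero —
the only reading consistent with using multiplicative (log-ratio) effect
sizes elsewhere. Note the numerator is log-scale while `s` carries outcome
units, so the standardized strength is *not* invariant to rescaling the
outcome; the numerator is, and tests pin both behaviours.

Two variance/CI modes:

* **printed** (default): `v = 1/n_W + 1/n_C + 1/n_B + 1/n_Cont +
  LnRR_Inter²/(2Σn)`, CI = estimate ± 1.96·√v. This is the conventional
  factorial-meta-analysis form; because its leading terms are not scaled by
  `s`, it is strongly conservative whenever arm SDs are small relative to
  means (CIs of half-width ≳2 against strengths of order 0.1), and under a
  multiplicative null essentially every quad is called additive.
* **delta** (calibrated): `v = [Σᵢ SDᵢ²/(nᵢ·x̄ᵢ²)]/(4s²)` with a Student-t
  critical value at the pooled degrees of freedom `Σnᵢ − 4` (the df behind
  the pooled SD). The `2s` standardization cancels in the test statistic,
  leaving a pooled-df t-test of the log-ratio contrast. A
  Welch–Satterthwaite df was rejected because it is systematically
  downward-biased under the equal-CV design (inflating null coverage to
  ~97%), and the Hedges-d-style `LnRR²/(2Σn)` term is omitted because it
  belongs to the sampling theory of d's `s`-standardization, not of a log
  contrast. This mode attains the nominal ~95% additive rate under a
  simulated multiplicative null and is the one used for type-I calibration
  studies.

Classification: **additive** if the CI contains zero; otherwise, with both
individual effects negative or of mixed sign, negative interaction ⇒
**synergistic**, positive ⇒ **antagonistic**. With both individual effects
positive the interpretation inverts (overshoot of two benefits is
synergism); such calls carry a `sign_inverted` flag rather than being
silently folded in, since the convention for that quadrant is not settled.

## Meta-analysis

Effect sizes are pooled per attribute × effect kind × driver context with
the multilevel model

    y_j = µ + u_study(j) + w_genus(j) + e_j,
    u ~ N(0, σ²_study),  w ~ N(0, σ²_genus),  e_j ~ N(0, v_j known),

study and genus entering as crossed random intercepts (a nested relabelling
is available; the two coincide when study labels are genus-unique).
Variance components are estimated by REML under non-negativity, optimized
by bounded L-BFGS-B from four deterministic starts (the DerSimonian–Laird
moment estimate split equally, each component alone, and zero), so fits are
reproducible and robust to boundary optima. The pooled mean is the GLS
estimate at the REML components with Wald (z) SE, CI and p-value — no
small-sample df correction, matching the significance convention the
pipeline mirrors. With both components forced to zero the fit reduces to
the classical fixed-effect inverse-variance mean (tested to 1e-8), and the
free optimum is audited against a 50×50 grid and independently against
metafor's `rma.mv` (agreement to ~1e-6 on shared fixtures).

Publication-bias support: leave-one-study-out refits flag reruns whose
significance verdict changes, and funnel coordinates flag effects outside
`|y_j − µ̂| ≤ 1.96·√(v_j + σ²_study + σ²_genus)`.

## Projections

A pooled activation energy is converted to an expected per cent change at a
warming `ΔT` through the inverse-thermal-energy increment `d(ΔT)`:

    percent_change = 100·(exp(−E·d) − 1),

and a pooled CO2 ratio through `100·(exp(LnRR₁₀₀·ΔpCO2/100) − 1)`. The
package stores percent change signed (negative = decline, the orientation
used when plotting against zero) and exposes `percent_decline` for the
positive-decline phrasing of results prose; declines are bounded above by
100%, increases are unbounded. CI bounds back-transform the Wald bounds of
the pooled effect; the exponential is monotone, so the order of bounds is
preserved and "CI excludes zero" is equivalent on either scale.

The `ΔT → Δ(1/kT)` map is fitted by OLS across the dataset's own
(ΔT, Δ(1/kT)) pairs, or evaluated analytically at a baseline temperature
when no records are supplied (default 27 °C, the midpoint of the 24–30 °C
control envelope, which reproduces the published survival back-transforms
to within rounding). The exact relation at fixed control temperature,
`d(ΔT) = ΔT/(k·T_o·(T_o+ΔT))`, is mildly concave, so a fitted line agrees
with the analytic curve only to the curvature scale (~3e-3 eV⁻¹ over a
5 °C span); with fewer than two usable warming records the fit falls back
to the analytic map with a warning.

**Threshold sensitivity.** The minimum driver increment producing a
significant change is found by scanning `step, 2·step, …, cap` (defaults
0.01 °C and 1 µatm, caps 13 °C and 800 µatm — the dataset envelopes).
Because the back-transform is monotone, under strict CI exclusion the
answer is either the first scanned increment or "none below the cap"; a
`rounded` rule (CI bounds rounded to a stated decimal before the zero
check) is provided as well, since finite, reporting-precision-dependent
thresholds can only arise when exclusion interacts with rounding. Neither
rule is asserted to be the one behind any published threshold; both are
exposed and the default is `exact`.

## Marine heatwaves

A MHW is a maximal run of days with daily SST strictly above a high
percentile (90th or 99th) of a designated baseline segment, summarized by
duration (exceedance days) and maximum intensity (largest anomaly above the
threshold). Choices, each configurable:

* the threshold is a single value from *all* baseline days (the detector
  thresholds against the baseline distribution, not a seasonal
  climatology); a day-of-year climatology mode with an 11-day window exists
  for comparison;
* `min_duration` defaults to 1 day (exceedance-day counting), with the
  conventional 5-day rule available;
* events separated by even one sub-threshold day are never joined (the
  simplest defensible rule);
* annual statistics attribute day counts to each day's calendar year and
  event-level statistics to the event's start year; with `min_duration = 1`
  and no boundary-crossing events, summed durations equal exceedance days.

Multi-model envelopes are element-wise mean/min/max across models per year.

## Synthetic data

The generators define the study conditions for every simulation-based
check. Experiment records draw control temperatures from 24–30 °C, warming
increments from +0.5 to +13 °C, control pCO2 from 297–486 µatm and
increments from +100 to +800 µatm — the envelopes of the experimental
literature the pipeline emulates. Outcome noise is lognormal
(mean/CV-parameterized, so arm means are unbiased and strictly positive, as
log ratios require) with default CV 0.15; arm sizes are 4–10 replicates;
between-study and between-genus heterogeneity are injected on the
effect-size scale so the meta-model has a known σ² truth; a pool of 10
genera reflects the concentration of coral experiments in a handful of
common genera. With sampling disabled (or CV 0) arms report exact latent
means, making record-level effect sizes recover latent effects to machine
precision — the oracle for the exactness tests.

The parameter-recovery study uses 40 studies × 2 effects, true E = 1.0 eV,
σ²_study = 0.05, σ²_genus = 0.02 and CV 0.2 (giving within-record variances
of order 0.02), 200 replicates; it checks Wald-CI coverage ≥ 0.90 and
systematic bias below 0.05 eV. Observed coverage sits near 91%, not the
nominal 95%: with only ~10 genus levels the Wald interval ignores real
variance-component uncertainty, a known property of z-based random-effects
intervals rather than an estimator defect (the estimator is unbiased to
~0.005 eV, and metafor's default behaves identically). The interaction
type-I study uses 2,000 multiplicative-null quads at n = 4/arm, CV 0.15,
classified in delta mode.

SST series are mean + sinusoidal seasonality + AR(1) noise + a linear trend
that is zero through the baseline and ramps afterwards, on a 365-day
(no-leap) calendar, plus additive injected heatwave blocks; the truth table
records each block's analytic exceedance-day count and maximum intensity
over the noise-free threshold (exact for noiseless specs, approximate
otherwise).

What the synthetic studies do *not* show: the generators emulate the
statistical structure of the literature (envelopes, heterogeneity,
lognormal noise), not its taxonomic composition, attribute imbalance,
publication filtering, or the spatial/temporal structure of real model SST
fields. Passing recovery tests therefore validates the estimators and the
pipeline plumbing, not any particular published pooled value; pooled
effects from real data remain dataset-dependent inputs.

## Problem sizes and determinism

Default analysis runs use 40 studies (~80 two-arm records), 100 factorial
quads, and three 40-year SST series — sizes at which every stage completes
in seconds while leaving enough replication per stratum for stable REML
fits. All randomness derives from a single integer seed; identical seeds
reproduce every output byte-for-byte.

## Known limitations

* Wald-z inference understates uncertainty when a random factor has few
  levels (see above); a Knapp–Hartung-style correction is out of scope.
* The printed-form interaction variance is conventional but conservative;
  classification proportions under it should be read as descriptive, not as
  calibrated hypothesis tests.
* The exact sensitivity-threshold rule behind published finite thresholds
  is not recoverable from reporting alone; both implemented rules are
  stated above.
* No gridded or regional projection: the pipeline operates on pooled,
  pantropical effect sizes and scenario increments supplied as
  configuration.
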