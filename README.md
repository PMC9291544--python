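# coralmeta

Meta-analytic projection of coral responses to intensifying marine
heatwaves (MHWs) and ocean acidification (OA).

Reef-building corals are being hit by two CO2-driven stressors at once:
episodes of extreme sea-surface temperature that trigger bleaching and
mortality, and the steady acidification of seawater. Experiments measure
how individual coral attributes — symbiont density, chlorophyll *a*,
photochemical efficiency, photosynthesis, respiration, calcification,
growth, survival — respond to imposed warming and elevated pCO2, but each
experiment uses its own species, temperatures and CO2 levels. `coralmeta`
is the machinery for turning a compilation of such experiments into
forward-looking, scenario-level projections, for meta-analysts and reef
scientists who want every step reproducible and testable on synthetic data
with known ground truth.

## What it computes

* **Effect sizes** — each warming contrast becomes an Arrhenius activation
  energy, `E = ln(V_o/V_i) / (1/kT_o − 1/kT_i)` (eV; positive = decline
  under warming), putting experiments run at different warming increments
  on a common per-unit-1/kT scale; each CO2 contrast becomes a log response
  ratio per +100 µatm, `LnRR₁₀₀ = (ln x̄_exp − ln x̄_cont)/ΔpCO2 × 100`.
  Delta-method sampling variances throughout.
* **Factorial interactions** — standardized interaction strength
  `[ln x̄_Both − ln x̄_W − ln x̄_CO2 + ln x̄_Cont]/(2s)` with 95% CI,
  classified additive / synergistic / antagonistic (zero for a
  multiplicative null).
* **Multilevel meta-analysis** — REML with crossed study and genus random
  intercepts and known sampling variances (verified against metafor's
  `rma.mv`), plus leave-one-study-out reruns and funnel diagnostics.
* **Scenario projections** — pooled effects back-transformed to expected
  per cent change, `100·(exp(−E·Δ(1/kT)) − 1)` under MHW warming and
  `100·(exp(LnRR₁₀₀·ΔpCO2/100) − 1)` under acidification, with
  CI-back-transformation, plus minimum-increment sensitivity scans.
* **MHW detection** — percentile-exceedance events in daily SST relative to
  a baseline segment, with durations, maximum intensities, annual
  statistics and multi-model envelopes.
* **Synthetic data** — generators for all of the above with truth tables,
  so estimator exactness, parameter recovery and CI calibration are
  testable end to end.

## Worked example

The analysis is organised as numbered drivers over the library:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_effect_sizes.py
python analysis/03_interactions.py
python analysis/04_meta_analysis.py
python analysis/05_projections.py
python analysis/06_mhw.py
```

`01` simulates 40 studies (80 two-arm records; true survival E = 0.7 eV,
symbiont density 1.5 eV, calcification LnRR₁₀₀ = −0.0197), 100
multiplicative-null factorial quads, and three 40-year SST series. The
downstream drivers then print, among other lines:

```
classified 100 factorial quads: {'additive': '100%', 'synergistic': '0%', 'antagonistic': '0%'}
  calcification     lnrr_co2    single_driver     -0.015 (95% CI -0.037..+0.007, k=130)  [truth -0.0197: inside CI]
  survival          arrhenius_E single_driver     +0.855 (95% CI +0.745..+0.964, k=27)  [truth 0.7: OUTSIDE CI]
  symbiont_density  arrhenius_E single_driver     +1.516 (95% CI +1.352..+1.680, k=23)  [truth 1.5: inside CI]
dT -> Delta(1/kT) map: fitted_from_data, slope 0.12325 eV^-1 per C (analytic slope at 27 C is ~0.1284)
survival, warming alone, late-century RCP8.5 (+4.32 C): 37.3% decline (95% CI 33.4..40.9%, significant=True)
multi-model mean MHW days/year (90th pct): 36.3 in the first decade vs 75.0 in the last (post-baseline trend +0.3 C/decade)
```

Reading this: every null quad is (correctly) called additive under the
conservative conventional CI; two of the three pooled effects cover their
generating truth while the survival stratum happens to miss on this seed
(its CI is a per-stratum 95% statement, not a guarantee — the dedicated
200-replicate recovery suite in `tests/test_acceptance.py` checks coverage
properly); the fitted temperature map tracks the analytic Arrhenius slope;
and the projected survival decline under the strongest late-century
scenario follows from the pooled 0.855 eV estimate. Everything is rerun
from a single seed; outputs land as tidy CSVs under `results/`.

A one-call orchestration of the same stages is available as
`coralmeta.run_pipeline(PipelineConfig(seed=...), outdir)`, which also
writes a JSON run manifest.

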