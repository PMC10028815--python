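# mimiclasso

Regularized MIMIC structural equation models for asking whether grey- and
white-matter brain metrics carry **redundant**, **independent**, or
**partially overlapping** information about cognitive performance.

## The problem

In developmental samples, cognitive ability correlates with many structural
brain measures at once: cortical thickness, surface area and grey-matter
volume over the 34 bilaterally averaged Desikan–Killiany parcels, and
fractional anisotropy, mean diffusivity and tract volume over 20
AtlasTrack-style white-matter tracts — 162 candidate predictors.  Studies
that model one tissue (or one metric) at a time cannot say whether the two
tissues explain the *same* variance or *complementary* variance.

`mimiclasso` implements the full analytic pipeline for that question:

1. **Measurement model.** A single latent factor g ("cognitive
   performance") measured by five task scores:
   y_j = ν_j + λ_j·g + ε_j, with one-factor CFA fit indices
   (χ², RMSEA, CFI, TLI, SRMR).
2. **MIMIC structural model.** Brain metrics x predict the latent factor:
   g = βᵀx + ζ, ζ ~ N(0, ψ), with the exogenous block saturated
   (μ_x, Σ_x free) so **FIML** covers missing cells in both indicators and
   predictors.  Estimation is quasi-Newton ML with analytic gradients;
   observed-information and Huber–White sandwich standard errors.
3. **Lasso-regularized paths.** The structural coefficients are penalized,
   min (−2/n)·ℓ(θ) + w·Σ|β_p|, solved by accelerated proximal gradient
   (soft-thresholding) over a 40-point log-spaced weight grid; BIC picks
   the weight; predictors with nonzero standardized paths "survive".
4. **Split-sample workflow.** 15% of subjects drive selection
   (model building); the survivors are refit freely on the held-out 85%
   (validation), yielding adjusted R², AIC/BIC, and likelihood-ratio tests
   of whole tissue blocks.
5. **Overlap classification.** The grey-only, white-only and combined
   adjusted R² values classify the scenario: *redundant*
   (combined ≈ max), *independent* (combined ≈ sum), *partial* (between).
6. **Stability selection.** Selection repeated over hundreds of fresh 15%
   subsamples gives each region/tract a survival percentage.
7. **Synthetic cohorts.** A first-class generator produces
   ABCD-release-structured tables (5 tasks, 162 predictors, TIV/sex/age,
   MCAR or MAR missingness) under each scenario, with closed-form
   population R² per tissue block for recovery testing.

## Worked example

```python
from mimiclasso import (make_design, generate_cohort, population_r2,
                        split_sample, select_and_validate, classify_overlap,
                        PipelineConfig, FAMILIES)

design = make_design("partial", n_subjects=6000, signal_strength=0.5,
                     seed=11, preset="tiny")
table, truth = generate_cohort(design)
split = split_sample(table, fraction=0.15, seed=5)
cfg = PipelineConfig(seed=5)
reports = {f: select_and_validate(split, table, f, cfg) for f in FAMILIES}
for fam in FAMILIES:
    print(fam, round(reports[fam].r2_adjusted, 3),
          "population", round(population_r2(design, fam), 3))
print(classify_overlap(reports["grey"].r2_adjusted,
                       reports["white"].r2_adjusted,
                       reports["combined"].r2_adjusted, delta=0.03))
```

prints

```
grey 0.358 population 0.375
white 0.389 population 0.375
combined 0.497 population 0.5
partial
```

— the validation-phase adjusted R² per family tracks the closed-form
population values, and the classifier recovers the generating scenario:
the combined model explains clearly more than either tissue alone but less
than their sum.

The numbered drivers under `analysis/` run the full study on the 162
predictor atlas: `01_simulate_cohorts.py` (three scenario cohorts),
`02_measurement_model.py`, `03_per_predictor_scan.py`,
`04_select_and_validate.py` (model-comparison table, block LRTs, equality
constraints, classification), `05_stability_selection.py` and
`06_sensitivity_covariates.py` (TIV, sex strata).  Each writes TSV/JSON
under `results/`.  The same operations are scriptable through the CLI
(`mimiclasso simulate|fit|regularize|scan|stability|pipeline`).

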