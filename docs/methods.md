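# Methods

## Model

The core model is a MIMIC (multiple-indicators-multiple-causes) structural
equation model.  Five observed task scores y measure one latent cognitive
factor g; a set of brain-metric predictors x (grey-matter cortical
thickness / surface area / volume over bilaterally averaged cortical
parcels; white-matter FA / MD / volume over tracts) predict the factor:

    g   = β'x + ζ,            ζ  ~ N(0, ψ)
    y_j = ν_j + λ_j g + ε_j,  ε_j ~ N(0, θ_j)

All modeled variables are treated as jointly multivariate normal.  The
exogenous predictors carry a saturated mean vector μ_x and covariance
Σ_x as free parameters, so the same full-information maximum-likelihood
(FIML) machinery covers missing cells in predictors as well as
indicators; rows contribute the normal log-density of their observed
subvector.  Under a missing-at-random mechanism this is the standard
consistent treatment of partial data.

Identification fixes the first loading to 1 (default) or fixes the latent
disturbance to 1; the two give identical fit (the χ² agrees to optimizer
tolerance) and the reporting surface is the standardized solution,
β_std = β·sd(x)/sd(g) and λ_std = λ·sd(g)/sd(y), with
sd(g) = √(β'Σ_xβ + ψ).

## Estimation

Two evaluation routes share one parameterisation:

* **Complete data** (or listwise deletion): the joint likelihood
  factorises into a saturated marginal for x — maximised exactly by the
  sample moments — and a conditional likelihood for y|x that depends only
  on (ν, λ, θ, β, ψ).  Fits then run on sufficient statistics and cost
  O(1) in the row count.
* **Missing data**: rows are grouped by missingness pattern, each pattern
  is summarised by its count/mean/scatter, and patterns of equal size are
  evaluated with batched linear algebra.  All parameters, including μ_x
  and the Cholesky factor of Σ_x (log-diagonal), are free.

Both routes use L-BFGS with analytic gradients; variances travel on the
log scale; convergence requires the per-observation gradient infinity-norm
below 1e-6 (configurable; max 5000 iterations, up to two perturbed
restarts).  Standard errors come from the observed information (finite
differences of the analytic gradient); an optional Huber–White sandwich
uses casewise FIML scores.  "Robust standard errors" here always means
this sandwich; no scaled χ² correction is applied to fit
indices (the chi-square is the plain likelihood-ratio against the
saturated model, whose moments come from EM when cells are missing).

Fit indices follow the usual definitions: RMSEA = √(max(χ²−df,0)/(df·n))
(with n, a convention choice), CFI and TLI against the independence
baseline (free means/variances, zero covariances), SRMR as the RMS
standardized residual of the covariance structure only (means are
saturated in every fitted model, diagonal included).  Degrees of freedom
count non-redundant covariance moments minus free covariance-structure
parameters; saturated means cancel.

## Penalized selection

Structural paths are selected with a lasso penalty:

    minimise  (−2/n)·loglik(θ) + w · Σ_{p penalized} |β_p|

by accelerated proximal gradient (FISTA) with backtracking line search and
adaptive restart; restarting on any objective increase makes the sequence
of accepted objective values non-increasing.  Predictors are standardized
to unit sample variance inside the fit, so the penalty (and the survival
threshold, |β_std| > 1e-3) is scale-free.  Unpenalized covariates (e.g.
TIV) are never thresholded.

The weight grid holds 40 log-spaced values from w_max — the smallest
weight at which the null model satisfies the stationarity conditions —
down three decades, fitted in decreasing order with warm starts.  The
weight is chosen by BIC with the number of nonzero penalized paths counted
as free parameters; ties go to the sparser model.  On the degenerate
single-indicator specification (λ=1, θ=0) the problem reduces exactly to
an observed-outcome lasso, which provides an independent coordinate-descent
oracle: at the joint optimum ψ̂ equals the residual variance and the
solution coincides with the lasso at α = w·ψ̂/2.

Two numerical guards matter in practice.  First, the penalized MIMIC
objective is non-convex and possesses a spurious basin in which the latent
disturbance ψ collapses toward zero with many small dense paths; the
solver therefore box-constrains the log-variance coordinates to two
decades around their moment-based starting values, which excludes the
degenerate basin without touching any realistic solution.  Second,
model-building fits are complete-case by default, but when the build rows
contain missing cells listwise deletion can collapse (at 162 predictors a
2% cell-wise rate leaves ~3% of rows complete); the pipeline then switches
the penalized problem to pairwise available-case moments — per-column
means and pairwise-complete covariances, eigenvalue-floored to positive
definite, feeding the complete-data objective.  This estimator is
consistent under MCAR, costs O(n q^2) whatever the missingness patterns,
and serves only the screening step.  Exact casewise penalized FIML remains
available as an option; validation-phase refits always use exact FIML.

## Split-sample workflow

A seeded uniform permutation assigns floor(0.15·n) subjects to the
model-building set and the rest to validation (a 15% split of 11,876 rows
gives 1,781 / 10,095).  Selection (path + BIC) runs per model family —
per-metric, grey (102 paths), white (60), combined (162) — on the build
set; the surviving regions/tracts are refit freely with FIML on the
validation set, yielding adjusted R² of the latent factor,

    R² = β'Σ_xβ / (β'Σ_xβ + ψ),
    R²_adj = 1 − (1−R²)(n−1)/(n−k−1),

AIC/BIC against the survivors-constrained-to-zero null, likelihood-ratio
tests of whole tissue blocks (paths fixed at zero, χ² df = number of
constrained paths), and an equality-constraint comparison (all surviving
paths forced equal on standardized predictors).

Because the likelihood includes the saturated exogenous block, information
criteria are comparable only between models over the same modeled
variables — the constrained-to-zero comparisons and the block LRTs, which
is where the model-selection inference lives.  Across families with
different predictor sets the comparison currency is the adjusted R² of
the latent factor.

**Overlap classification.**  Given grey, white and combined adjusted R²,
the scenario is *redundant* if combined − max ≤ δ, *independent* if
(grey + white) − combined ≤ δ, else *partially overlapping*; when both
margins hold the smaller slack wins, exact ties read redundant.
δ defaults to 0.01 absolute adjusted-R² units.  For the end-to-end
recovery experiments and the analysis drivers we classify with δ = 0.03:
the standard error of an R² estimate near 0.25 at a ~5,000-row validation
sample is ≈0.01 and the additive margin combines three such estimates, so
a 0.01 margin sits below the noise floor of the quantities compared, while
the generator's population slacks (≤0.005 for redundant, ≥0.1 for
partial) keep δ = 0.03 unambiguous.

**Stability selection.**  Selection is repeated on fresh random
fraction-sized subsamples, iteration i seeded base_seed + i, so the
procedure is order-independent and parallel-safe; per-predictor survival
percentages are reported over successful iterations (failures are counted
and excluded from the denominator).  Fast mode (default) reuses the
penalty weight chosen once on the full sample; faithful mode reruns path
and selection inside every iteration at ~40x the cost.

**Sensitivity runs** repeat the pipeline with TIV as an unpenalized third
predictor, with TIV as the sole predictor, and within each stratum of a
grouping column (sex).

Per-predictor scans (one single-predictor MIMIC fit per region × metric)
report standardized paths with raw Wald p-values plus Benjamini–Hochberg
adjusted values.

## Synthetic cohorts

The generator emulates the tabulated structure of a large developmental
imaging release: five task indicators with standardized loadings
(0.74, 0.70, 0.53, 0.47, 0.41), 34×3 grey + 20×3 white predictors (17
tracts bilaterally averaged plus 3 midline), TIV/sex/age covariates, and
missing cells.  Predictors are jointly Gaussian: each loads on a single
cross-tissue shared factor plus independent unique noise, all population
variances one, which makes the population R² of any block a closed-form
projection, r² = c_B' Σ_BB⁻¹ c_B / Var(g) with c_B = (Σ_x β)_B.

Scenario constructions are symmetric across tissues:

* *independent*: signal predictors are mutually orthogonal, split across
  tissues — tissue R²s add exactly;
* *redundant*: signal predictors are (nearly) rescaled copies of the
  shared factor.  With unique variance exactly zero the textbook identity
  combined = grey = white holds but Σ_x is rank-deficient and the
  saturated likelihood no longer exists, so the default keeps a 0.02
  unique-variance floor (identity within 0.005); `unique_floor=0` gives
  the exact construction for population-level work;
* *partial*: signal predictors carry a shared loading of √0.2, placing
  the combined R² ≥0.1 above the best single tissue and ≥0.2 below the
  sum — well clear of both classification margins.

`signal_strength` is the population combined R² (default 0.5, "strong");
the per-predictor coefficient follows from the number of signal predictors
per tissue (6 on the full atlas, 4 on the tiny preset).  Missingness is
opt-in: MCAR per cell at a given rate (default 0), or a MAR mode in which
the missingness probability rises with the (always observed) age
covariate — the mechanism under which FIML is still valid.  TIV correlates
with the predictive signal at 0.37 by default, so a TIV-only model
explains ≈7% of latent variance.  A chi-square unique-noise flag provides
a non-Gaussian stress mode.

What the generator does *not* emulate: site/scanner effects, spatial
autocorrelation on the cortical surface, realistic atlas covariance
geometry, sex-dependent effect sizes, or non-linear brain–behaviour
relations.  Passing recovery tests therefore demonstrates correctness of
the estimator under its own assumptions, not robustness to those
real-data features.

## Problem sizes and test scale

The test suite runs the full workflow at desk scale: the tiny atlas preset
(4 parcels, 3 tracts — 21 predictors) for the end-to-end suites, cohorts
of 2,000–6,000 subjects, 100 seeded cohorts per scenario for recovery,
500 replicates for LRT type-I calibration, 200 stability iterations.  The
analysis drivers run the full 162-predictor atlas at n = 6,000.

## Known limitations

* The penalized objective is non-convex; the proximal solver finds a
  stationary point, warm starts make the path reproducible, and the KKT
  conditions are verified in tests, but global optimality is not
  guaranteed away from the degenerate-spec (lasso) case.
* Equality and zero constraints apply only to structural paths; loadings
  and variances are never penalized or constrained across groups (no
  multi-group SEM, no ordinal indicators, no Satorra–Bentler scaling).
* Two-stage (EM-moments) penalized selection is an approximation to exact
  penalized FIML; the validation phase, which produces all reported
  inference, always uses exact FIML.
* Adjusted R² uses the number of free structural predictors as k; with
  selection the validation-phase R² carries the usual mild winner's-curse
  optimism, mitigated but not removed by the split-sample design.
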