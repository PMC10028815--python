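"""The end-to-end split-sample workflow.

Mirrors the study design the package supports: a random model-building
subsample (default 15%) is used to run the lasso path and pick the
surviving regions/tracts; the held-out validation sample refits those
survivors freely (FIML), yielding fit indices, adjusted R-squared,
tissue-block likelihood-ratio tests and information-criterion comparisons;
repeated subsampling turns the selection step into per-predictor survival
percentages; and the three family-level R-squareds classify the grey/white
overlap scenario (redundant / independent / partially overlapping).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import penalty as pn
from .fit import (FitOptions, FitResult, FitIndices, fit_free, fit_indices,
                  likelihood_ratio_test, rsquare_latent)
from .model import ModelSpec, ModelError, mimic_spec

FAMILIES = ("grey", "white", "combined")


@dataclasses.dataclass
class SplitResult:
    """Disjoint build/validation partition of the row indices."""

    build_rows: np.ndarray
    validation_rows: np.ndarray
    fraction: float
    seed: int


@dataclasses.dataclass
class PipelineConfig:
    indicators: tuple[str, ...] = ()
    fraction: float = 0.15
    seed: int = 0
    delta: float = 0.01          # scenario-classification tolerance (adj. R2)
    criterion: str = "bic"
    zero_tolerance: float = 1e-3
    grid_size: int = 40
    grid_ratio: float = 1e-3
    prox_tol: float = 1e-8
    stability_mode: str = "fast"     # or "faithful": reselect per iteration
    n_iterations: int = 1000
    compute_se: bool = False
    covariate: str = "tiv"
    strata: str = "sex"

    def penalty_options(self) -> pn.PenaltyOptions:
        return pn.PenaltyOptions(tol=self.prox_tol,
                                 zero_tolerance=self.zero_tolerance,
                                 grid_size=self.grid_size,
                                 grid_ratio=self.grid_ratio)

    def fit_options(self) -> FitOptions:
        return FitOptions(se=self.compute_se)


@dataclasses.dataclass
class ValidationReport:
    family: str
    survivor_set: pn.SurvivorSet | None
    fit: FitResult | None
    indices: FitIndices | None
    r2: float
    r2_adjusted: float
    block_lrts: list[tuple[str, float, int, float]]
    aic_comparison: dict
    skipped: bool
    validation_rows: np.ndarray | None
    label: str = ""

    def summary(self) -> dict:
        return {
            "family": self.family,
            "label": self.label,
            "skipped": self.skipped,
            "n_survivors": 0 if self.survivor_set is None
            else len(self.survivor_set.names),
            "survivors": [] if self.survivor_set is None
            else list(self.survivor_set.names),
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "fit_indices": None if self.indices is None
            else self.indices.as_dict(),
            "block_lrts": [
                {"block": b, "statistic": s, "df": d, "p": p}
                for b, s, d, p in self.block_lrts],
            "aic_comparison": self.aic_comparison,
        }


@dataclasses.dataclass
class StabilityTable:
    table: pd.DataFrame           # index predictor, column survival_percentage
    n_iterations: int
    subsample_fraction: float
    base_seed: int
    n_failures: int
    penalty_weight: float


# ---------------------------------------------------------------------------

def split_sample(data: pd.DataFrame, fraction: float, seed: int) -> SplitResult:
    """Uniform random split: the first floor(fraction * n) rows of a seeded
    permutation form the model-building set."""
    if not 0.0 <= fraction < 1.0:
        raise ModelError("fraction must lie in [0, 1)")
    n = len(data)
    perm = np.random.default_rng(seed).permutation(n)
    n_build = int(np.floor(fraction * n))
    return SplitResult(build_rows=np.sort(perm[:n_build]),
                       validation_rows=np.sort(perm[n_build:]),
                       fraction=fraction, seed=seed)


def family_predictors(predictors, family: str) -> tuple[str, ...]:
    """Resolve a model family to its predictor columns.

    ``grey`` / ``white`` / ``combined`` select by tissue; ``metric:<tissue>.
    <metric>`` (e.g. ``metric:grey.thickness``) selects one metric."""
    predictors = tuple(predictors)
    if family == "combined":
        return predictors
    if family in ("grey", "white"):
        out = tuple(p for p in predictors if p.startswith(family + "."))
    elif family.startswith("metric:"):
        prefix = family.split(":", 1)[1] + "."
        out = tuple(p for p in predictors if p.startswith(prefix))
    else:
        raise ModelError(f"unknown model family {family!r}")
    if not out:
        raise ModelError(f"no predictors for family {family!r}")
    return out


def _tissue_of(name: str) -> str:
    return name.split(".", 1)[0]


def _penalty_options_for(config: PipelineConfig, data: pd.DataFrame,
                         spec: ModelSpec) -> pn.PenaltyOptions:
    """Model-building fits are complete-case on complete data; when the
    build rows carry missing cells, high predictor counts make listwise
    deletion collapse, so the penalized problem switches to pairwise
    available-case moments (PD-repaired, consistent under MCAR)."""
    popt = config.penalty_options()
    if data[list(spec.modeled)].isna().any().any():
        popt.missing = "pairwise_moments"
    return popt


def per_predictor_scan(data: pd.DataFrame, base_spec: ModelSpec,
                       options: FitOptions | None = None) -> pd.DataFrame:
    """One single-predictor MIMIC fit per region/tract x metric.

    Reports the standardized path, its raw-scale Wald test and
    Benjamini-Hochberg adjusted p-values.  Non-converged fits are kept in
    the table with NaN estimates so the scan always has one row per
    predictor.
    """
    if base_spec.p < 1:
        raise ModelError("scan requires at least one predictor")
    options = options or FitOptions(se=True)
    rows = []
    for name in base_spec.predictors:
        spec1 = mimic_spec(base_spec.indicators, (name,),
                           covariates=tuple(c for c in base_spec.covariates
                                            if c != name),
                           identification=base_spec.identification,
                           missing=base_spec.missing)
        try:
            fit = fit_free(spec1, data, dataclasses.replace(options, se=True))
            se = fit.se.get(f"beta[{name}]") if fit.se else float("nan")
            beta = float(fit.estimates.beta[list(spec1.predictors).index(name)])
            z = beta / se if se and se > 0 else float("nan")
            from scipy.stats import norm
            pval = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else float("nan")
            rows.append({
                "predictor": name, "tissue": _tissue_of(name),
                "beta_std": fit.standardized["beta"][name],
                "beta": beta, "se": se, "p": pval,
                "converged": fit.converged,
            })
        except (ModelError, np.linalg.LinAlgError):
            rows.append({"predictor": name, "tissue": _tissue_of(name),
                         "beta_std": float("nan"), "beta": float("nan"),
                         "se": float("nan"), "p": float("nan"),
                         "converged": False})
    out = pd.DataFrame(rows).set_index("predictor")
    ok = out["p"].notna()
    out["p_bh"] = float("nan")
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def select_and_validate(split: SplitResult, data: pd.DataFrame, family: str,
                        config: PipelineConfig) -> ValidationReport:
    """Penalized selection on the build rows, free FIML refit of the
    survivors on the validation rows."""
    indicators = tuple(config.indicators) or _default_indicators(data)
    preds = family_predictors(_brain_predictors(data), family)
    build = data.iloc[split.build_rows]
    spec_build = mimic_spec(indicators, preds)
    popt = _penalty_options_for(config, build, spec_build)
    path = pn.fit_path(spec_build, build, options=popt)
    chosen = pn.select_penalty(path, config.criterion)
    surv = pn.survivors(chosen, config.zero_tolerance, family=family)

    if not surv.names:
        return ValidationReport(family=family, survivor_set=surv, fit=None,
                                indices=None, r2=float("nan"),
                                r2_adjusted=float("nan"), block_lrts=[],
                                aic_comparison={}, skipped=True,
                                validation_rows=split.validation_rows)

    val = data.iloc[split.validation_rows]
    spec_val = mimic_spec(indicators, surv.names, penalized=())
    fit = fit_free(spec_val, val, config.fit_options())
    try:
        indices = fit_indices(fit, val)
    except (np.linalg.LinAlgError, FloatingPointError):
        indices = None
    r2, r2a = rsquare_latent(fit)

    # information criteria against the same model with all survivor paths
    # constrained to zero (the no-brain-effect null)
    null_fit = fit_free(spec_val.replace(zero_paths=surv.names), val,
                        config.fit_options())
    aic_cmp = {
        "aic_free": fit.aic, "aic_null": null_fit.aic,
        "bic_free": fit.bic, "bic_null": null_fit.bic,
        "preferred_aic": "free" if fit.aic <= null_fit.aic else "null",
        "preferred_bic": "free" if fit.bic <= null_fit.bic else "null",
    }

    report = ValidationReport(family=family, survivor_set=surv, fit=fit,
                              indices=indices, r2=r2, r2_adjusted=r2a,
                              block_lrts=[], aic_comparison=aic_cmp,
                              skipped=False,
                              validation_rows=split.validation_rows)
    if family == "combined":
        tissues = {_tissue_of(n) for n in surv.names}
        for block in sorted(tissues):
            if len(tissues) < 2:
                break
            stat, df, p = tissue_block_lrt(report, data, block)
            report.block_lrts.append((block, stat, df, p))
    return report


def tissue_block_lrt(report: ValidationReport, data: pd.DataFrame,
                     block: str):
    """LRT of the validation model against the same model with the named
    tissue's surviving paths constrained to zero."""
    if report.skipped or report.fit is None:
        raise ModelError("report has no validation fit")
    surv = report.survivor_set.names
    zeroed = tuple(n for n in surv if _tissue_of(n) == block)
    if not zeroed:
        raise ModelError(f"no surviving {block!r} paths to constrain")
    val = data.iloc[report.validation_rows]
    spec0 = report.fit.spec.replace(
        zero_paths=tuple(set(report.fit.spec.zero_paths) | set(zeroed)))
    fit0 = fit_free(spec0, val, FitOptions(se=False))
    return likelihood_ratio_test(report.fit, fit0)


def classify_overlap(r2_grey: float, r2_white: float, r2_combined: float,
                     delta: float = 0.01) -> str:
    """Classify the grey/white information overlap from three R-squareds.

    redundant   : combined - max(grey, white) <= delta
    independent : (grey + white) - combined   <= delta
    partial     : otherwise (strictly between the two limits)

    If both conditions hold the smaller slack wins; an exact tie is called
    redundant (the more parsimonious reading).
    """
    for v in (r2_grey, r2_white, r2_combined):
        if not 0.0 <= v < 1.0:
            raise ModelError("R-squared inputs must lie in [0, 1)")
    if delta <= 0:
        raise ModelError("delta must be positive")
    hi = max(r2_grey, r2_white)
    slack_red = r2_combined - hi
    slack_ind = (r2_grey + r2_white) - r2_combined
    if slack_red < -delta:
        raise ModelError(
            "inconsistent input: combined R-squared falls below the best "
            "single-tissue value by more than delta")
    red = slack_red <= delta
    ind = slack_ind <= delta
    if red and ind:
        return "redundant" if slack_red <= slack_ind else "independent"
    if red:
        return "redundant"
    if ind:
        return "independent"
    return "partial"


@dataclasses.dataclass
class EqualityComparison:
    aic_free: float
    aic_equal: float
    bic_free: float
    bic_equal: float
    preferred: dict


def equality_constraint_comparison(report: ValidationReport,
                                   data: pd.DataFrame) -> EqualityComparison:
    """Free survivor paths vs. all survivor paths constrained equal.

    Predictor columns are standardized on the validation rows first so the
    equality constraint compares standardized effects.
    """
    if report.skipped or report.survivor_set is None \
            or len(report.survivor_set.names) < 2:
        raise ModelError("equality comparison needs at least two survivors")
    surv = report.survivor_set.names
    val = data.iloc[report.validation_rows].copy()
    for c in surv:
        sd = val[c].std(ddof=0)
        val[c] = (val[c] - val[c].mean()) / sd
    spec_free = report.fit.spec
    free_fit = fit_free(spec_free, val, FitOptions(se=False))
    equal_fit = fit_free(spec_free.replace(equal_paths=surv), val,
                         FitOptions(se=False))
    return EqualityComparison(
        aic_free=free_fit.aic, aic_equal=equal_fit.aic,
        bic_free=free_fit.bic, bic_equal=equal_fit.bic,
        preferred={
            "aic": "free" if free_fit.aic <= equal_fit.aic else "equal",
            "bic": "free" if free_fit.bic <= equal_fit.bic else "equal",
        })


def stability_selection(data: pd.DataFrame, family: str, n_iterations: int,
                        fraction: float, base_seed: int,
                        config: PipelineConfig | None = None) -> StabilityTable:
    """Repeated regularization over fresh random subsamples.

    Iteration ``i`` draws floor(fraction * n) rows with seed
    ``base_seed + i`` and records which penalized paths survive; the table
    holds per-predictor survival percentages.  In ``fast`` mode the penalty
    weight is selected once on the full sample and reused; ``faithful``
    mode reruns path and selection inside every iteration.
    """
    if n_iterations < 1:
        raise ModelError("n_iterations must be at least 1")
    config = config or PipelineConfig()
    indicators = tuple(config.indicators) or _default_indicators(data)
    preds = family_predictors(_brain_predictors(data), family)
    spec = mimic_spec(indicators, preds)
    popt = _penalty_options_for(config, data, spec)

    full_path = pn.fit_path(spec, data, options=popt)
    chosen = pn.select_penalty(full_path, config.criterion)
    weight = chosen.penalty_weight

    n = len(data)
    n_sub = int(np.floor(fraction * n))
    counts = {p: 0 for p in spec.penalized}
    failures = 0
    successes = 0
    for i in range(n_iterations):
        rows = np.random.default_rng(base_seed + i).permutation(n)[:n_sub]
        sub = data.iloc[np.sort(rows)]
        try:
            if config.stability_mode == "fast":
                f = pn.fit_penalized(spec, sub, weight, popt, warm=chosen)
                if not f.converged:
                    raise ModelError("penalized fit did not converge")
            else:
                path_i = pn.fit_path(spec, sub, options=popt)
                f = pn.select_penalty(path_i, config.criterion)
            sv = pn.survivors(f, config.zero_tolerance)
        except (ModelError, np.linalg.LinAlgError):
            failures += 1
            continue
        successes += 1
        for nme in sv.names:
            counts[nme] += 1
    if successes == 0:
        raise ModelError("every stability iteration failed")
    pct = {p: 100.0 * c / successes for p, c in counts.items()}
    table = pd.DataFrame({"survival_percentage": pd.Series(pct)})
    table.index.name = "predictor"
    return StabilityTable(table=table, n_iterations=successes,
                          subsample_fraction=fraction, base_seed=base_seed,
                          n_failures=failures, penalty_weight=weight)


def covariate_and_strata_runs(data: pd.DataFrame,
                              config: PipelineConfig) -> list[ValidationReport]:
    """Sensitivity reruns: TIV as unpenalized covariate, TIV as the sole
    predictor, and the full pipeline within each stratum (e.g. sex)."""
    cov, strata = config.covariate, config.strata
    for col in (cov, strata):
        if col not in data.columns:
            raise ModelError(f"column {col!r} not present in data")
    indicators = tuple(config.indicators) or _default_indicators(data)
    reports = []

    split = split_sample(data, config.fraction, config.seed)

    # (a) combined family with the covariate as an unpenalized extra path
    preds = family_predictors(_brain_predictors(data), "combined")
    build = data.iloc[split.build_rows]
    spec_b = mimic_spec(indicators, preds + (cov,), covariates=(cov,))
    path = pn.fit_path(spec_b, build,
                       options=_penalty_options_for(config, build, spec_b))
    chosen = pn.select_penalty(path, config.criterion)
    surv = pn.survivors(chosen, config.zero_tolerance, family="combined")
    val = data.iloc[split.validation_rows]
    spec_v = mimic_spec(indicators, surv.names + (cov,), covariates=(cov,),
                        penalized=())
    fit = fit_free(spec_v, val, config.fit_options())
    r2, r2a = rsquare_latent(fit)
    reports.append(ValidationReport(
        family="combined", survivor_set=surv, fit=fit,
        indices=None, r2=r2, r2_adjusted=r2a, block_lrts=[],
        aic_comparison={}, skipped=False,
        validation_rows=split.validation_rows, label=f"combined+{cov}"))

    # (b) covariate as the sole predictor
    spec_c = mimic_spec(indicators, (cov,), penalized=())
    fit_c = fit_free(spec_c, val, config.fit_options())
    r2c, r2ca = rsquare_latent(fit_c)
    reports.append(ValidationReport(
        family="covariate_only", survivor_set=None, fit=fit_c, indices=None,
        r2=r2c, r2_adjusted=r2ca, block_lrts=[], aic_comparison={},
        skipped=False, validation_rows=split.validation_rows,
        label=f"{cov}_only"))

    # (c) per-stratum rerun of the standard combined pipeline
    for value in sorted(data[strata].dropna().unique()):
        sub = data[data[strata] == value].reset_index(drop=True)
        sp = split_sample(sub, config.fraction, config.seed)
        rep = select_and_validate(sp, sub, "combined", config)
        rep.label = f"{strata}={value}"
        reports.append(rep)
    return reports


# ---------------------------------------------------------------------------

def _default_indicators(data: pd.DataFrame) -> tuple[str, ...]:
    from .cohort import DEFAULT_INDICATORS
    missing = [c for c in DEFAULT_INDICATORS if c not in data.columns]
    if missing:
        raise ModelError(f"indicator columns not found: {missing}")
    return DEFAULT_INDICATORS


def _brain_predictors(data: pd.DataFrame) -> tuple[str, ...]:
    preds = tuple(c for c in data.columns
                  if c.startswith("grey.") or c.startswith("white."))
    if not preds:
        raise ModelError("no grey.*/white.* predictor columns in data")
    return preds
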