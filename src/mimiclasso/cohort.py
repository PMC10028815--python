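"""Synthetic cohorts with the structure the MIMIC analyses assume.

The generator emulates a large developmental-cohort tabulated release: one
latent cognitive factor measured by five task scores, grey-matter metrics
(cortical thickness, surface area, volume) over 34 bilaterally averaged
cortical parcels, white-matter metrics (FA, MD, volume) over 20 tracts,
optional covariates (TIV, sex, age), and missing cells.

Predictors are jointly Gaussian: each predictor loads on a single
cross-tissue shared factor and carries independent unique noise, which
keeps every population R-squared available in closed form.  The three
overlap scenarios are built symmetrically across tissues:

* ``redundant``   — all predictive signal routes through the shared factor,
  so either tissue recovers (essentially) everything the other offers;
* ``independent`` — signal predictors are mutually orthogonal and split
  across tissues, so the tissue R-squareds add exactly;
* ``partial``     — signal predictors carry both a shared and a unique
  component, so the combined R-squared lies strictly between the maximum
  and the sum of the single-tissue values.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

# 34 Desikan-Killiany cortical parcels (bilaterally averaged)
DESIKAN_PARCELS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal",
    "lingual", "medialorbitofrontal", "middletemporal", "parahippocampal",
    "paracentral", "parsopercularis", "parsorbitalis", "parstriangularis",
    "pericalcarine", "postcentral", "posteriorcingulate", "precentral",
    "precuneus", "rostralanteriorcingulate", "rostralmiddlefrontal",
    "superiorfrontal", "superiorparietal", "superiortemporal",
    "supramarginal", "frontalpole", "temporalpole", "transversetemporal",
    "insula",
)

# 20 white-matter tracts: 17 bilaterally averaged plus 3 midline
TRACTS_PAIRED = (
    "fornix", "cingulum_cingulate", "cingulum_parahippocampal",
    "corticospinal", "anterior_thalamic", "uncinate",
    "inferior_longitudinal", "inferior_fronto_occipital",
    "superior_longitudinal", "temporal_superior_longitudinal",
    "superior_corticostriate", "superior_corticostriate_frontal",
    "superior_corticostriate_parietal", "striatal_inferior_frontal",
    "inferior_frontal_superior_frontal", "fimbria", "parahippocampal",
)
TRACTS_MIDLINE = ("corpus_callosum", "forceps_major", "forceps_minor")
TRACTS = TRACTS_PAIRED + TRACTS_MIDLINE

GREY_METRICS = ("thickness", "area", "volume")
WHITE_METRICS = ("fa", "md", "volume")

# indicators ordered by their standardized loading
DEFAULT_INDICATORS = ("oral_reading", "pic_vocab", "ravlt", "little_man",
                      "flanker")
DEFAULT_LOADINGS = (0.74, 0.70, 0.53, 0.47, 0.41)

SCENARIOS = ("redundant", "independent", "partial")
BLOCKS = ("grey", "white", "combined")

# desk-scale preset for fast test runs
TINY_PARCELS = DESIKAN_PARCELS[:4]
TINY_TRACTS = TRACTS_PAIRED[:2] + TRACTS_MIDLINE[:1]


class DesignError(ValueError):
    pass


def predictor_name(tissue: str, metric: str, region: str) -> str:
    return f"{tissue}.{metric}.{region}"


def predictor_names(parcels=DESIKAN_PARCELS, tracts=TRACTS) -> tuple[str, ...]:
    names = [predictor_name("grey", m, r) for m in GREY_METRICS for r in parcels]
    names += [predictor_name("white", m, t) for m in WHITE_METRICS for t in tracts]
    return tuple(names)


@dataclasses.dataclass
class CohortDesign:
    """Complete description of one synthetic cohort.

    All predictors have unit population variance; the latent factor has
    unit population variance (psi = 1 - Var(x'beta)); indicators have unit
    population variance, so the design loadings are standardized loadings.
    """

    n_subjects: int
    grey_parcels: tuple[str, ...]
    white_tracts: tuple[str, ...]
    grey_metrics: tuple[str, ...]
    white_metrics: tuple[str, ...]
    loadings: tuple[float, ...]
    indicator_residuals: tuple[float, ...]
    true_beta: dict[str, float]
    shared_factor_loadings: dict[str, float]
    unique_variances: dict[str, float]
    latent_disturbance: float
    scenario: str
    missing_rate: float
    seed: int
    indicators: tuple[str, ...] = DEFAULT_INDICATORS
    missing_mode: str = "mcar"          # or "mar": probability driven by age
    nongaussian_unique: bool = False    # chi-square unique noise stress mode
    tiv_signal_corr: float = 0.37       # corr(TIV, standardized x'beta)

    def __post_init__(self):
        if self.n_subjects < 2:
            raise DesignError("n_subjects must be at least 2")
        if self.scenario not in SCENARIOS:
            raise DesignError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise DesignError("missing_rate must lie in [0, 1)")
        if self.latent_disturbance <= 0:
            raise DesignError("latent disturbance must be positive")
        if any(v <= 0 for v in self.indicator_residuals):
            raise DesignError("indicator residual variances must be positive")
        if any(v < 0 for v in self.unique_variances.values()):
            raise DesignError("unique variances must be non-negative")
        expected = set(predictor_names(self.grey_parcels, self.white_tracts))
        for field in (self.true_beta, self.shared_factor_loadings,
                      self.unique_variances):
            if set(field) != expected:
                raise DesignError("predictor maps must cover exactly the "
                                  "parcel x metric and tract x metric grid")

    @property
    def predictors(self) -> tuple[str, ...]:
        return predictor_names(self.grey_parcels, self.white_tracts)

    @property
    def grey_predictors(self) -> tuple[str, ...]:
        return tuple(n for n in self.predictors if n.startswith("grey."))

    @property
    def white_predictors(self) -> tuple[str, ...]:
        return tuple(n for n in self.predictors if n.startswith("white."))

    def beta_vector(self) -> np.ndarray:
        return np.array([self.true_beta[n] for n in self.predictors])

    def sigma_x(self) -> np.ndarray:
        """Population predictor covariance: s s' + diag(unique)."""
        s = np.array([self.shared_factor_loadings[n] for n in self.predictors])
        u = np.array([self.unique_variances[n] for n in self.predictors])
        return np.outer(s, s) + np.diag(u)


@dataclasses.dataclass
class GroundTruth:
    latent_scores: np.ndarray
    true_beta: dict[str, float]
    population_r2: dict[str, float]
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "true_beta": self.true_beta,
            "population_r2": self.population_r2,
            "latent_scores": [round(float(v), 10) for v in self.latent_scores],
        }, sort_keys=True, indent=1)


def _signal_indices(n_region: int, k: int) -> np.ndarray:
    """Evenly spread k signal regions over a block of n_region regions."""
    return np.unique(np.linspace(0, n_region - 1, k).round().astype(int))


def make_design(scenario: str, n_subjects: int, signal_strength: float = 0.5,
                seed: int = 0, preset: str = "full", missing_rate: float = 0.0,
                n_signal_per_tissue: int | None = None,
                unique_floor: float = 0.02, **kw) -> CohortDesign:
    """Build a scenario design.

    ``signal_strength`` is the population R-squared of the latent factor on
    the combined predictor set.  ``unique_floor`` is the unique variance
    retained by redundant-scenario signal predictors; 0 gives the exact
    textbook construction (combined = grey = white) at the price of a
    rank-deficient predictor covariance.
    """
    if scenario not in SCENARIOS:
        raise DesignError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if signal_strength <= 0 or signal_strength >= 1:
        raise DesignError("signal_strength must lie in (0, 1)")
    if preset == "full":
        parcels, tracts = DESIKAN_PARCELS, TRACTS
        k = n_signal_per_tissue or 6
    elif preset == "tiny":
        parcels, tracts = TINY_PARCELS, TINY_TRACTS
        k = n_signal_per_tissue or 4
    else:
        raise DesignError(f"unknown preset {preset!r}")

    names = predictor_names(parcels, tracts)
    grey = [n for n in names if n.startswith("grey.")]
    white = [n for n in names if n.startswith("white.")]
    k = min(k, len(grey), len(white))
    signal = [grey[i] for i in _signal_indices(len(grey), k)] \
        + [white[i] for i in _signal_indices(len(white), k)]

    shared = {n: 0.0 for n in names}
    unique = {n: 1.0 for n in names}
    beta = {n: 0.0 for n in names}

    if scenario == "independent":
        a = 0.0
    elif scenario == "redundant":
        a = float(np.sqrt(1.0 - unique_floor))
    else:
        # partial: a modest shared component leaves the combined R-squared
        # well separated from both the redundant and the additive limit
        a = float(np.sqrt(0.2))
    for nme in signal:
        shared[nme] = a
        unique[nme] = 1.0 - a * a

    # Var(x'beta) = (sum beta*a)^2 + sum beta^2*unique = s for equal betas b:
    #   b^2 * ((2k a)^2 + 2k (1 - a^2)) = signal_strength
    denom = (2 * k * a) ** 2 + 2 * k * (1.0 - a * a)
    b = float(np.sqrt(signal_strength / denom))
    for nme in signal:
        beta[nme] = b

    psi = 1.0 - signal_strength
    loadings = tuple(kw.pop("loadings", DEFAULT_LOADINGS))
    residuals = tuple(kw.pop("indicator_residuals",
                             tuple(1.0 - l * l for l in loadings)))
    return CohortDesign(
        n_subjects=n_subjects, grey_parcels=tuple(parcels),
        white_tracts=tuple(tracts), grey_metrics=GREY_METRICS,
        white_metrics=WHITE_METRICS, loadings=loadings,
        indicator_residuals=residuals, true_beta=beta,
        shared_factor_loadings=shared, unique_variances=unique,
        latent_disturbance=psi, scenario=scenario,
        missing_rate=missing_rate, seed=seed, **kw)


def population_r2(design: CohortDesign, block: str) -> float:
    """Population R-squared of the latent factor from one predictor block.

    The best linear predictor of g from block B has variance
    c_B' pinv(Sigma_BB) c_B with c_B = Cov(x_B, g) = (Sigma_x beta)_B;
    divide by Var(g) = beta' Sigma_x beta + psi.
    """
    names = design.predictors
    if block == "grey":
        sel = [i for i, n in enumerate(names) if n.startswith("grey.")]
    elif block == "white":
        sel = [i for i, n in enumerate(names) if n.startswith("white.")]
    elif block == "combined":
        sel = list(range(len(names)))
    else:
        raise DesignError(f"unknown block {block!r}; expected one of {BLOCKS}")
    Sigma = design.sigma_x()
    beta = design.beta_vector()
    var_g = float(beta @ Sigma @ beta) + design.latent_disturbance
    c = (Sigma @ beta)[sel]
    Sbb = Sigma[np.ix_(sel, sel)]
    proj = float(c @ np.linalg.pinv(Sbb, hermitian=True) @ c)
    return proj / var_g


def design_parameters(design: CohortDesign):
    """The generating values as a :class:`~mimiclasso.model.Parameters`
    object over (indicators, predictors) — handy for recovery tests."""
    from .model import Parameters
    lam = np.asarray(design.loadings, float)
    theta = np.asarray(design.indicator_residuals, float)
    return Parameters(lam=lam, nu=np.zeros(lam.size), theta=theta,
                      beta=design.beta_vector(), psi=design.latent_disturbance,
                      mu_x=np.zeros(len(design.predictors)),
                      sigma_x=design.sigma_x())


def generate_cohort(design: CohortDesign):
    """Draw one cohort; returns ``(table, ground_truth)``.

    Identical designs (including the seed) give bit-identical tables.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_subjects
    names = design.predictors
    p = len(names)
    s = np.array([design.shared_factor_loadings[m] for m in names])
    u = np.array([design.unique_variances[m] for m in names])
    beta = design.beta_vector()
    lam = np.asarray(design.loadings, float)
    theta = np.asarray(design.indicator_residuals, float)

    f = rng.standard_normal(n)
    if design.nongaussian_unique:
        # centred, scaled chi-square(4) noise: unit variance, skewed
        eps = (rng.chisquare(4, size=(n, p)) - 4.0) / np.sqrt(8.0)
    else:
        eps = rng.standard_normal((n, p))
    X = np.outer(f, s) + eps * np.sqrt(u)

    xb = X @ beta
    zeta = rng.standard_normal(n) * np.sqrt(design.latent_disturbance)
    g = xb + zeta
    y = lam * g[:, None] + rng.standard_normal((n, lam.size)) * np.sqrt(theta)

    # covariates: TIV correlated with the predictive signal, sex and age
    sd_xb = float(np.sqrt(beta @ design.sigma_x() @ beta))
    rho = design.tiv_signal_corr
    tiv_noise = rng.standard_normal(n)
    if sd_xb > 0 and abs(rho) > 0:
        tiv = rho * xb / sd_xb + np.sqrt(1.0 - rho ** 2) * tiv_noise
    else:
        tiv = tiv_noise
    sex = np.where(rng.random(n) < 0.48, "F", "M")
    age = 9.9 + 0.6 * rng.standard_normal(n)

    table = pd.concat(
        [pd.DataFrame({"subject_id": [f"S{i + 1:06d}" for i in range(n)]}),
         pd.DataFrame(y, columns=list(design.indicators)),
         pd.DataFrame(X, columns=list(names)),
         pd.DataFrame({"tiv": tiv, "sex": sex, "age": age})],
        axis=1)

    if design.missing_rate > 0:
        cols = list(design.indicators) + list(names)
        if design.missing_mode == "mcar":
            mask = rng.random((n, len(cols))) < design.missing_rate
        elif design.missing_mode == "mar":
            # older children are likelier to have missing cells; the rate
            # averages to missing_rate across the age distribution
            z = (age - 9.9) / 0.6
            row_rate = design.missing_rate * np.exp(0.8 * z)
            row_rate = row_rate * (design.missing_rate / row_rate.mean())
            mask = rng.random((n, len(cols))) < np.clip(row_rate, 0, 0.95)[:, None]
        else:
            raise DesignError(f"unknown missing mode {design.missing_mode!r}")
        # keep at least one observed modeled value per row
        all_gone = mask.all(axis=1)
        if all_gone.any():
            keep = rng.integers(0, len(cols), size=int(all_gone.sum()))
            mask[np.flatnonzero(all_gone), keep] = False
        vals = table[cols].to_numpy()
        vals[mask] = np.nan
        table[cols] = vals

    truth = GroundTruth(
        latent_scores=g,
        true_beta=dict(design.true_beta),
        population_r2={blk: population_r2(design, blk) for blk in BLOCKS},
        seed=design.seed)
    return table, truth
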