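"""Model specifications and parameter bookkeeping for MIMIC models.

A MIMIC (multiple-indicators-multiple-causes) model here is: observed
brain-metric predictors x feed a single latent cognitive factor g, which is
measured by a small set of observed task indicators y:

    g   = beta' x + zeta,        zeta ~ N(0, psi)
    y_j = nu_j + lambda_j g + eps_j,  eps_j ~ N(0, theta_j)

The exogenous predictors carry a saturated mean vector and covariance
matrix, so missing predictor cells are covered by the same FIML machinery
as missing indicators.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

IDENT_FIRST_LOADING = "first_loading_fixed_1"
IDENT_LATENT_VARIANCE = "latent_variance_fixed_1"
MISSING_FIML = "fiml"
MISSING_COMPLETE = "complete_case"


class ModelError(ValueError):
    """Invalid model specification or parameter set."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one CFA/MIMIC model.

    ``penalized`` names the structural paths subject to the lasso penalty;
    ``covariates`` are unpenalized structural predictors (e.g. TIV).
    ``zero_paths`` fixes the named structural coefficients to zero and
    ``equal_paths`` constrains the named coefficients to share one value —
    both used by the validation-phase model comparisons.
    """

    indicators: tuple[str, ...]
    predictors: tuple[str, ...] = ()
    penalized: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    identification: str = IDENT_FIRST_LOADING
    mean_structure: bool = True
    missing: str = MISSING_FIML
    zero_paths: tuple[str, ...] = ()
    equal_paths: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))
        object.__setattr__(self, "predictors", tuple(self.predictors))
        object.__setattr__(self, "penalized", tuple(self.penalized))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "zero_paths", tuple(self.zero_paths))
        object.__setattr__(self, "equal_paths", tuple(self.equal_paths))
        if len(self.indicators) < 2 and len(self.indicators) != 1:
            raise ModelError("at least one indicator is required")
        if len(set(self.indicators)) != len(self.indicators):
            raise ModelError("duplicate indicator names")
        if len(set(self.predictors)) != len(self.predictors):
            raise ModelError("duplicate predictor names")
        preds = set(self.predictors)
        for group, label in ((self.penalized, "penalized"),
                             (self.covariates, "covariates"),
                             (self.zero_paths, "zero_paths"),
                             (self.equal_paths, "equal_paths")):
            unknown = set(group) - preds
            if unknown:
                raise ModelError(f"{label} not among predictors: {sorted(unknown)}")
        if set(self.penalized) & set(self.covariates):
            raise ModelError("penalized paths and covariates must be disjoint")
        if self.identification not in (IDENT_FIRST_LOADING, IDENT_LATENT_VARIANCE):
            raise ModelError(f"unknown identification {self.identification!r}")
        if self.missing not in (MISSING_FIML, MISSING_COMPLETE):
            raise ModelError(f"unknown missing strategy {self.missing!r}")

    @property
    def m(self) -> int:
        return len(self.indicators)

    @property
    def p(self) -> int:
        return len(self.predictors)

    @property
    def degenerate(self) -> bool:
        """Single observed outcome: loading fixed to 1, no measurement error
        (the model collapses to a linear regression)."""
        return self.m == 1

    @property
    def modeled(self) -> tuple[str, ...]:
        return self.indicators + self.predictors

    def free_beta_count(self) -> int:
        p_free = self.p - len(self.zero_paths)
        if self.equal_paths:
            p_free -= len(set(self.equal_paths) - set(self.zero_paths)) - 1
        return p_free

    def replace(self, **kw) -> "ModelSpec":
        return dataclasses.replace(self, **kw)


def mimic_spec(indicators, predictors=(), covariates=(), **kw) -> ModelSpec:
    """Convenience constructor: every non-covariate predictor is penalized."""
    predictors = tuple(predictors)
    covariates = tuple(covariates)
    penalized = kw.pop("penalized", tuple(x for x in predictors if x not in covariates))
    return ModelSpec(tuple(indicators), predictors, tuple(penalized),
                     covariates, **kw)


def measurement_spec(indicators, **kw) -> ModelSpec:
    """One-factor confirmatory factor model (no structural predictors)."""
    return ModelSpec(tuple(indicators), **kw)


@dataclasses.dataclass
class Parameters:
    """All free quantities of the MIMIC likelihood."""

    lam: np.ndarray
    nu: np.ndarray
    theta: np.ndarray
    beta: np.ndarray
    psi: float
    mu_x: np.ndarray
    sigma_x: np.ndarray

    def __post_init__(self):
        self.lam = np.atleast_1d(np.asarray(self.lam, float))
        self.nu = np.atleast_1d(np.asarray(self.nu, float))
        self.theta = np.atleast_1d(np.asarray(self.theta, float))
        self.beta = np.asarray(self.beta, float).reshape(-1)
        self.mu_x = np.asarray(self.mu_x, float).reshape(-1)
        self.sigma_x = np.atleast_2d(np.asarray(self.sigma_x, float))
        self.psi = float(self.psi)

    def validate(self, spec: ModelSpec):
        m, p = spec.m, spec.p
        if self.lam.shape != (m,) or self.nu.shape != (m,) or self.theta.shape != (m,):
            raise ModelError("measurement parameter shapes do not match spec")
        if self.beta.shape != (p,) or self.mu_x.shape != (p,):
            raise ModelError("structural parameter shapes do not match spec")
        if self.sigma_x.shape != (p, p):
            raise ModelError("sigma_x shape does not match spec")
        if np.any(self.theta < 0) or self.psi < 0:
            raise ModelError("variances must be non-negative")

    @property
    def latent_variance(self) -> float:
        return float(self.beta @ self.sigma_x @ self.beta + self.psi)

    def copy(self) -> "Parameters":
        return Parameters(self.lam.copy(), self.nu.copy(), self.theta.copy(),
                          self.beta.copy(), self.psi, self.mu_x.copy(),
                          self.sigma_x.copy())


def implied_moments(spec: ModelSpec, params: Parameters):
    """Model-implied mean vector and covariance matrix over (y, x).

    Var(g) = beta' Sigma_x beta + psi
    Cov(y) = lam lam' Var(g) + diag(theta)
    Cov(y, x) = lam (beta' Sigma_x)
    """
    params.validate(spec)
    m, p = spec.m, spec.p
    if p:
        try:
            np.linalg.cholesky(params.sigma_x)
        except np.linalg.LinAlgError as exc:
            raise ModelError("sigma_x is not positive definite") from exc
    v = params.latent_variance
    c = params.sigma_x @ params.beta
    q = m + p
    mu = np.empty(q)
    mu[:m] = params.nu + params.lam * float(params.beta @ params.mu_x)
    mu[m:] = params.mu_x
    Sigma = np.empty((q, q))
    Sigma[:m, :m] = v * np.outer(params.lam, params.lam) + np.diag(params.theta)
    Sigma[:m, m:] = np.outer(params.lam, c)
    Sigma[m:, :m] = Sigma[:m, m:].T
    Sigma[m:, m:] = params.sigma_x
    return mu, 0.5 * (Sigma + Sigma.T)


def count_df(spec: ModelSpec) -> int:
    """Covariance-structure degrees of freedom: non-redundant modeled
    moments minus free parameters.  Mean structure is saturated in every
    model here (free intercepts and free exogenous means), so the mean
    moments cancel and only the covariance structure counts.  A negative
    value (more parameters than moments) triggers a warning."""
    m, p = spec.m, spec.p
    q = m + p
    moments = q * (q + 1) // 2
    if spec.degenerate:
        k_lam, k_theta = 0, 0
    elif spec.identification == IDENT_FIRST_LOADING:
        k_lam, k_theta = m - 1, m
    else:
        k_lam, k_theta = m, m
    k_psi = 0 if spec.identification == IDENT_LATENT_VARIANCE and not spec.degenerate else 1
    k = k_lam + k_theta + k_psi + spec.free_beta_count() + p * (p + 1) // 2
    df = moments - k
    if df < 0:
        warnings.warn(f"model is not identified: df = {df} < 0", stacklevel=2)
    return df


def count_free(spec: ModelSpec) -> int:
    """Total free parameters including the saturated mean structure and the
    exogenous moments — the count used by AIC/BIC."""
    m, p = spec.m, spec.p
    df_cov_params = (spec.m + spec.p) * (spec.m + spec.p + 1) // 2 - count_df(spec)
    return df_cov_params + m + p  # + saturated means (nu, mu_x)


class ParameterMap:
    """Pack/unpack between :class:`Parameters` and a free vector.

    Variance parameters travel on the log scale.  When ``free_x`` is set
    the exogenous moments are free (FIML with missing predictor cells) and
    Sigma_x is parameterised by its Cholesky factor with log-diagonal;
    otherwise they are held fixed at values supplied to :meth:`unpack`
    (complete-data profiling, where the sample moments are the ML solution).
    """

    def __init__(self, spec: ModelSpec, free_x: bool):
        self.spec = spec
        self.free_x = free_x
        m, p = spec.m, spec.p
        self._beta_kind = []
        equal = set(spec.equal_paths) - set(spec.zero_paths)
        seen_equal = False
        for name in spec.predictors:
            if name in spec.zero_paths:
                self._beta_kind.append("zero")
            elif name in equal:
                self._beta_kind.append("equal_lead" if not seen_equal else "equal")
                seen_equal = True
            else:
                self._beta_kind.append("free")
        self.n_beta_free = sum(k == "free" for k in self._beta_kind) + int(seen_equal)

        self.free_lam_idx = (() if spec.degenerate else
                             tuple(range(1, m)) if spec.identification == IDENT_FIRST_LOADING
                             else tuple(range(m)))
        self.free_theta = not spec.degenerate
        self.free_psi = not (spec.identification == IDENT_LATENT_VARIANCE
                             and not spec.degenerate)

        sl, off = {}, 0

        def add(name, size):
            nonlocal off
            sl[name] = slice(off, off + size)
            off += size

        add("nu", m)
        add("lam", len(self.free_lam_idx))
        add("log_theta", m if self.free_theta else 0)
        add("beta", self.n_beta_free)
        add("log_psi", 1 if self.free_psi else 0)
        if free_x:
            add("mu_x", p)
            add("chol_x", p * (p + 1) // 2)
        self.slices = sl
        self.k = off
        self._tril = np.tril_indices(p)

    # -- packing -----------------------------------------------------------
    def pack(self, params: Parameters) -> np.ndarray:
        sl = self.slices
        x = np.empty(self.k)
        x[sl["nu"]] = params.nu
        x[sl["lam"]] = params.lam[list(self.free_lam_idx)]
        if self.free_theta:
            x[sl["log_theta"]] = np.log(np.maximum(params.theta, 1e-12))
        x[sl["beta"]] = self._pack_beta(params.beta)
        if self.free_psi:
            x[sl["log_psi"]] = np.log(max(params.psi, 1e-12))
        if self.free_x:
            x[sl["mu_x"]] = params.mu_x
            L = np.linalg.cholesky(params.sigma_x)
            vals = L[self._tril]
            diag_pos = np.flatnonzero(self._tril[0] == self._tril[1])
            vals = vals.copy()
            vals[diag_pos] = np.log(np.maximum(np.diag(L), 1e-12))
            x[sl["chol_x"]] = vals
        return x

    def _pack_beta(self, beta):
        out = []
        lead_done = False
        for b, kind in zip(beta, self._beta_kind):
            if kind == "free":
                out.append(b)
            elif kind == "equal_lead":
                out.append(b)
                lead_done = True
        return np.array(out) if out else np.empty(0)

    # -- unpacking ---------------------------------------------------------
    def unpack(self, x: np.ndarray, mu_x=None, sigma_x=None) -> Parameters:
        spec, sl = self.spec, self.slices
        m, p = spec.m, spec.p
        nu = np.asarray(x[sl["nu"]], float).copy()
        if spec.degenerate:
            lam = np.ones(1)
            theta = np.zeros(1)
        else:
            lam = np.ones(m)
            lam[list(self.free_lam_idx)] = x[sl["lam"]]
            theta = np.exp(np.clip(x[sl["log_theta"]], -40, 40))
        beta = self._unpack_beta(x[sl["beta"]], p)
        psi = float(np.exp(np.clip(x[sl["log_psi"]][0], -40, 40))) if self.free_psi else 1.0
        if self.free_x:
            mu_x = np.asarray(x[sl["mu_x"]], float).copy()
            L = np.zeros((p, p))
            vals = np.asarray(x[sl["chol_x"]], float).copy()
            diag_pos = np.flatnonzero(self._tril[0] == self._tril[1])
            vals[diag_pos] = np.exp(np.clip(vals[diag_pos], -40, 40))
            L[self._tril] = vals
            sigma_x = L @ L.T
        else:
            if mu_x is None or sigma_x is None:
                raise ModelError("fixed exogenous moments must be supplied")
        return Parameters(lam, nu, theta, beta, psi, mu_x, sigma_x)

    def _unpack_beta(self, bfree, p):
        beta = np.zeros(p)
        it = iter(np.atleast_1d(bfree))
        shared = None
        free_vals = list(np.atleast_1d(bfree))
        pos = 0
        for i, kind in enumerate(self._beta_kind):
            if kind == "free":
                beta[i] = free_vals[pos]
                pos += 1
            elif kind == "equal_lead":
                shared = free_vals[pos]
                beta[i] = shared
                pos += 1
            elif kind == "equal":
                beta[i] = 0.0  # filled after the lead is known
        if shared is not None:
            for i, kind in enumerate(self._beta_kind):
                if kind == "equal":
                    beta[i] = shared
        return beta

    # -- gradient chain ----------------------------------------------------
    def chain(self, params: Parameters, d: dict, x: np.ndarray) -> np.ndarray:
        """Map gradients w.r.t. natural parameters into free-vector space.

        ``d`` holds 'nu', 'lam', 'theta', 'psi', 'beta' (natural scale) and,
        when ``free_x``, 'mu_x' and 'sigma_x' (full symmetric matrix
        gradient).
        """
        sl = self.slices
        g = np.zeros(self.k)
        g[sl["nu"]] = d["nu"]
        if self.free_lam_idx:
            g[sl["lam"]] = d["lam"][list(self.free_lam_idx)]
        if self.free_theta:
            g[sl["log_theta"]] = d["theta"] * params.theta
        g[sl["beta"]] = self._chain_beta(d["beta"])
        if self.free_psi:
            g[sl["log_psi"]] = d["psi"] * params.psi
        if self.free_x:
            g[sl["mu_x"]] = d["mu_x"]
            G = d["sigma_x"]
            L = np.linalg.cholesky(params.sigma_x)
            GL = (G + G.T) @ L
            vals = GL[self._tril]
            diag_pos = np.flatnonzero(self._tril[0] == self._tril[1])
            vals = vals.copy()
            vals[diag_pos] = vals[diag_pos] * np.diag(L)
            g[sl["chol_x"]] = vals
        return g

    def _chain_beta(self, dbeta):
        out = []
        shared = 0.0
        has_equal = False
        for db, kind in zip(dbeta, self._beta_kind):
            if kind == "free":
                out.append(db)
            elif kind in ("equal_lead", "equal"):
                shared += db
                has_equal = True
        if has_equal:
            # shared parameter sits at the position of the lead
            res = []
            pos = 0
            for db, kind in zip(dbeta, self._beta_kind):
                if kind == "free":
                    res.append(out[pos])
                    pos += 1
                elif kind == "equal_lead":
                    res.append(shared)
            return np.array(res)
        return np.array(out) if out else np.empty(0)

    def penalized_positions(self) -> np.ndarray:
        """Positions in the free vector of the penalized structural paths."""
        spec = self.spec
        base = self.slices["beta"].start
        pos = []
        free_i = 0
        pen = set(spec.penalized)
        for name, kind in zip(spec.predictors, self._beta_kind):
            if kind == "free":
                if name in pen:
                    pos.append(base + free_i)
                free_i += 1
            elif kind == "equal_lead":
                free_i += 1
        return np.array(pos, dtype=int)
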