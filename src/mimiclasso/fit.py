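"""Maximum-likelihood fitting of CFA/MIMIC models.

Two evaluation routes share one parameterisation:

* complete data (or complete-case deletion): the saturated exogenous block
  is profiled out at the sample moments and only the conditional
  parameters (nu, lambda, theta, beta, psi) are optimised — evaluations
  depend on the data through sufficient statistics only;
* missing data (FIML): all parameters, including the exogenous mean and
  the Cholesky factor of the exogenous covariance, are optimised against
  the pattern-wise likelihood.

Quasi-Newton (L-BFGS-B) maximisation with analytic gradients; variances on
the log scale; convergence when the infinity-norm of the per-observation
gradient drops below ``gtol``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from . import likelihood as lk
from .model import (ModelSpec, Parameters, ParameterMap, ModelError,
                    implied_moments, count_df, count_free,
                    IDENT_LATENT_VARIANCE, MISSING_COMPLETE)


class ConvergenceError(RuntimeError):
    pass


@dataclasses.dataclass
class FitOptions:
    gtol: float = 1e-6
    max_iter: int = 5000
    se: bool = True
    robust: bool = False
    n_restarts: int = 2


@dataclasses.dataclass
class FitResult:
    """Converged (or flagged) ML solution of one model."""

    spec: ModelSpec
    estimates: Parameters
    loglik: float
    loglik_cond: float
    n_used: int
    k_free: int
    converged: bool
    se: dict | None = None
    se_robust: dict | None = None
    standardized: dict | None = None
    grad_norm: float = float("nan")
    rows_used: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_free

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k_free * np.log(self.n_used)


@dataclasses.dataclass
class FitIndices:
    chisq: float
    df: int
    rmsea: float
    cfi: float
    tli: float
    srmr: float
    aic: float
    bic: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _extract(spec: ModelSpec, data: pd.DataFrame):
    cols = list(spec.modeled)
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ModelError(f"columns absent from data: {missing_cols}")
    X = data[cols].to_numpy(dtype=float)
    if spec.missing == MISSING_COMPLETE:
        keep = ~np.isnan(X).any(axis=1)
    else:
        keep = ~np.isnan(X).all(axis=1)
    return X[keep], np.flatnonzero(keep)


def loglik_fiml(spec: ModelSpec, params: Parameters, data: pd.DataFrame) -> float:
    """FIML log-likelihood of ``params`` on ``data`` (sum over rows of the
    observed-subvector log density).  A row with no observed modeled
    variable violates the contract and is rejected."""
    cols = list(spec.modeled)
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ModelError(f"columns absent from data: {missing_cols}")
    X = data[cols].to_numpy(dtype=float)
    pdata = lk.pattern_data(X, spec.modeled)
    mu, Sigma = implied_moments(spec, params)
    return lk.mvn_loglik(mu, Sigma, pdata)


# ---------------------------------------------------------------------------
# objective closures
# ---------------------------------------------------------------------------

def _full_chain(spec, params, gmu, gS, pmap):
    """Contract FIML gradients w.r.t. (mu, Sigma) into natural parameters."""
    m = spec.m
    lam, beta = params.lam, params.beta
    Gyy, Gyx, Gxx = gS[:m, :m], gS[:m, m:], gS[m:, m:]
    gy, gx = gmu[:m], gmu[m:]
    a = Gyy @ lam
    s = float(lam @ a)
    b = Gyx.T @ lam
    c = params.sigma_x @ beta
    v = params.latent_variance
    t = float(beta @ params.mu_x)
    w = float(lam @ gy)
    # gS is a full symmetric-matrix gradient, so perturbations of the two
    # off-diagonal (indicator x predictor) blocks each contribute once
    d = {
        "nu": gy.copy(),
        "lam": 2.0 * v * a + 2.0 * Gyx @ c + t * gy,
        "theta": np.diag(Gyy).copy(),
        "psi": s,
        "beta": 2.0 * s * c + 2.0 * params.sigma_x @ b + w * params.mu_x,
    }
    if pmap.free_x:
        M = Gxx + np.outer(beta, b) + np.outer(b, beta) \
            + s * np.outer(beta, beta)
        d["sigma_x"] = M
        d["mu_x"] = gx + w * beta
    return d


def _make_objective_fiml(spec, pmap, pdata):
    n = pdata.n

    def fun(x):
        params = pmap.unpack(x)
        try:
            mu, Sigma = implied_moments(spec, params)
            ll, gmu, gS = lk.mvn_loglik(mu, Sigma, pdata, grad=True)
        except (lk.SingularPatternError, ModelError):
            return np.inf, np.zeros(pmap.k)
        d = _full_chain(spec, params, gmu, gS, pmap)
        g = pmap.chain(params, d, x)
        return -ll / n, -g / n

    return fun


def _make_objective_cond(spec, pmap, stats):
    n = stats.n

    def fun(x):
        params = pmap.unpack(x, mu_x=stats.xbar, sigma_x=stats.Sxx)
        try:
            out = lk.conditional_loglik(stats, params.nu, params.lam,
                                        params.theta, params.psi,
                                        params.beta, grad=True)
        except lk.SingularPatternError:
            return np.inf, np.zeros(pmap.k)
        ll, d = out
        g = pmap.chain(params, d, x)
        return -ll / n, -g / n

    return fun


# ---------------------------------------------------------------------------
# initial values
# ---------------------------------------------------------------------------

def initial_params(spec: ModelSpec, mean: np.ndarray, cov: np.ndarray) -> Parameters:
    """Cheap, deterministic starting values from (possibly EM-smoothed)
    moments: triad estimate of the latent variance, marker-scaled loadings,
    least-squares structural paths."""
    m, p = spec.m, spec.p
    ybar, xbar = mean[:m], mean[m:]
    Syy = cov[:m, :m]
    Syx = cov[:m, m:]
    Sxx = cov[m:, m:]

    if spec.degenerate:
        lam = np.ones(1)
        theta = np.zeros(1)
        beta = (np.linalg.lstsq(Sxx, Syx[0], rcond=None)[0]
                if p else np.empty(0))
        resid = float(Syy[0, 0] - (beta @ Syx[0] if p else 0.0))
        psi = max(resid, 0.05 * float(Syy[0, 0]) + 1e-8)
        nu = np.array([ybar[0] - float(beta @ xbar)]) if p else ybar.copy()
        return Parameters(lam, nu, theta, beta, psi,
                          xbar.copy(), Sxx.copy())

    # triad estimate of Var(g) on the first-loading scale
    v = 0.5 * float(Syy[0, 0])
    if m >= 3 and abs(Syy[1, 2]) > 1e-12:
        tri = Syy[0, 1] * Syy[0, 2] / Syy[1, 2]
        if np.isfinite(tri) and tri > 1e-8:
            v = float(min(tri, 0.95 * Syy[0, 0]))
    lam = np.ones(m)
    lam[1:] = Syy[0, 1:] / v
    theta = np.maximum(np.diag(Syy) - lam ** 2 * v, 0.05 * np.diag(Syy))
    if p:
        target = (Syx.T @ lam) / max(float(lam @ lam), 1e-8)
        beta = np.linalg.lstsq(Sxx, target, rcond=None)[0]
        explained = float(beta @ Sxx @ beta)
    else:
        beta = np.empty(0)
        explained = 0.0
    psi = max(v - explained, 0.1 * v)
    if spec.identification == IDENT_LATENT_VARIANCE:
        # rescale to the psi = 1 identification
        scale = np.sqrt(v)
        lam = lam * scale
        beta = beta * scale / np.sqrt(max(explained * scale ** 2 / v + 1.0, 1e-8)) \
            if p else beta
        psi = 1.0
    nu = ybar - lam * float(beta @ xbar) if p else ybar.copy()
    return Parameters(lam, nu, theta, beta, psi, xbar.copy(), Sxx.copy())


# ---------------------------------------------------------------------------
# main fit
# ---------------------------------------------------------------------------

def fit_free(spec: ModelSpec, data: pd.DataFrame,
             options: FitOptions | None = None) -> FitResult:
    """Fit the model by (full-information) maximum likelihood."""
    options = options or FitOptions()
    X, rows = _extract(spec, data)
    n = X.shape[0]
    k_free = count_free(spec)
    if n <= pmap_size_guard(spec):
        raise ModelError(f"n = {n} rows is too small to fit {k_free} parameters")

    has_missing = bool(np.isnan(X).any())
    if has_missing:
        pdata = lk.pattern_data(X, spec.modeled)
        mu0, Sigma0, _ = lk.em_saturated(pdata)
        pmap = ParameterMap(spec, free_x=True)
        init = initial_params(spec, mu0, Sigma0)
        # keep the Cholesky parameterisation well-defined
        init.sigma_x = nearest_pd(init.sigma_x)
        fun = _make_objective_fiml(spec, pmap, pdata)
        fixed = {}
    else:
        stats = lk.MomentData.from_matrix(X, spec.modeled, spec.m)
        cov = np.block([[stats.Syy, stats.Syx],
                        [stats.Syx.T, stats.Sxx]])
        mean = np.concatenate([stats.ybar, stats.xbar])
        pmap = ParameterMap(spec, free_x=False)
        init = initial_params(spec, mean, cov)
        fun = _make_objective_cond(spec, pmap, stats)
        fixed = {"mu_x": stats.xbar, "sigma_x": stats.Sxx}

    x0 = pmap.pack(init)
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(1 + options.n_restarts):
        xs = x0 if attempt == 0 else x0 + rng.normal(0, 0.1, size=x0.size)
        res = scipy.optimize.minimize(
            fun, xs, jac=True, method="L-BFGS-B",
            options={"maxiter": options.max_iter, "ftol": 1e-14,
                     "gtol": options.gtol, "maxcor": 30})
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        if best is None or res.fun < best[0].fun - 1e-12:
            best = (res, gnorm)
        if gnorm <= options.gtol * 10:
            best = (res, gnorm)
            break
    res, gnorm = best
    converged = bool(np.isfinite(res.fun)) and gnorm <= options.gtol * 10

    params = pmap.unpack(res.x, **fixed)
    if has_missing:
        mu, Sigma = implied_moments(spec, params)
        ll = lk.mvn_loglik(mu, Sigma, pdata)
        stats_for_cond = None
        ll_cond = float("nan")
    else:
        ll_cond = lk.conditional_loglik(stats, params.nu, params.lam,
                                        params.theta, params.psi, params.beta)
        ll = ll_cond + lk.xblock_loglik(n, stats.Sxx)
        stats_for_cond = stats

    fit = FitResult(spec=spec, estimates=params, loglik=ll, loglik_cond=ll_cond,
                    n_used=n, k_free=k_free, converged=converged,
                    grad_norm=gnorm, rows_used=rows)
    fit.standardized = standardized_solution(fit)
    if options.se:
        fit.se = _observed_info_se(fun, res.x, pmap, params, n)
    if options.robust:
        fit.se_robust = _sandwich_se(spec, params, X, pmap, fun, res.x, n,
                                     fixed)
    return fit


def pmap_size_guard(spec: ModelSpec) -> int:
    # free conditional parameters; exogenous moments are matched exactly
    return ParameterMap(spec, free_x=False).k


def nearest_pd(S: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    if S.size == 0:
        return S
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    w = np.maximum(w, eps * max(w.max(), 1.0))
    return (V * w) @ V.T


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def _named_free(pmap: ParameterMap):
    spec = pmap.spec
    names = []
    names += [f"nu[{s}]" for s in spec.indicators]
    names += [f"lam[{spec.indicators[i]}]" for i in pmap.free_lam_idx]
    if pmap.free_theta:
        names += [f"theta[{s}]" for s in spec.indicators]
    seen_lead = False
    for name, kind in zip(spec.predictors, pmap._beta_kind):
        if kind == "free":
            names.append(f"beta[{name}]")
        elif kind == "equal_lead":
            names.append("beta[<equal>]")
    if pmap.free_psi:
        names.append("psi")
    if pmap.free_x:
        names += [f"mu_x[{s}]" for s in spec.predictors]
        names += [f"chol_x[{i}]" for i in range(pmap.slices["chol_x"].stop
                                                - pmap.slices["chol_x"].start)]
    return names


def _hessian_fd(fun, x, scale=1.0):
    """Central finite differences of the analytic gradient."""
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        h = 1e-5 * (1.0 + abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        gp = fun(xp)[1]
        gm = fun(xm)[1]
        H[i] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    return H * scale


def _se_from_cov(pmap, params, cov, names):
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    # delta method back to natural scale for log-parameterised variances
    sl = pmap.slices
    if pmap.free_theta:
        se[sl["log_theta"]] = se[sl["log_theta"]] * params.theta
    if pmap.free_psi:
        se[sl["log_psi"]] = se[sl["log_psi"]] * params.psi
    return dict(zip(names, se))


def _observed_info_se(fun, x, pmap, params, n):
    H = _hessian_fd(fun, x, scale=n)     # Hessian of -loglik
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        return None
    return _se_from_cov(pmap, params, cov, _named_free(pmap))


def _sandwich_se(spec, params, X, pmap, fun, x, n, fixed):
    """Huber-White sandwich: H^{-1} (sum_i s_i s_i') H^{-1} with casewise
    FIML scores."""
    scores = casewise_scores(spec, params, X, pmap, fixed)
    H = _hessian_fd(fun, x, scale=n)
    Hinv = np.linalg.pinv(H)
    B = scores.T @ scores
    cov = Hinv @ B @ Hinv
    return _se_from_cov(pmap, params, cov, _named_free(pmap))


def casewise_scores(spec: ModelSpec, params: Parameters, X: np.ndarray,
                    pmap: ParameterMap, fixed: dict | None = None) -> np.ndarray:
    """Per-row score vectors d log f_i / d(free parameters)."""
    mu, Sigma = implied_moments(spec, params)
    n, q = X.shape
    x_at = pmap.pack(params)
    obs = ~np.isnan(X)
    scores = np.empty((n, pmap.k))
    for i in range(n):
        o = np.flatnonzero(obs[i])
        Soo = Sigma[np.ix_(o, o)]
        Si = np.linalg.inv(Soo)
        d = X[i, o] - mu[o]
        u = Si @ d
        gmu = np.zeros(q)
        gmu[o] = u
        gS = np.zeros((q, q))
        gS[np.ix_(o, o)] = 0.5 * (np.outer(u, u) - Si)
        dnat = _full_chain(spec, params, gmu, gS, pmap)
        scores[i] = pmap.chain(params, dnat, x_at)
    return scores


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def standardized_solution(fit: FitResult) -> dict:
    """Standardized loadings and structural paths.

    beta_std = beta * sd(x) / sd(g); lam_std = lam * sd(g) / sd(y).
    """
    params = fit.estimates
    spec = fit.spec
    v = params.latent_variance
    if v <= 0:
        raise ModelError("implied latent variance is not positive")
    sd_g = np.sqrt(v)
    sd_y = np.sqrt(params.lam ** 2 * v + params.theta)
    if np.any(sd_y <= 0):
        raise ModelError("implied indicator variance is not positive")
    lam_std = params.lam * sd_g / sd_y
    sd_x = np.sqrt(np.diag(params.sigma_x)) if spec.p else np.empty(0)
    beta_std = params.beta * sd_x / sd_g
    return {
        "lam": dict(zip(spec.indicators, lam_std)),
        "beta": dict(zip(spec.predictors, beta_std)),
        "latent_sd": sd_g,
    }


def rsquare_latent(fit: FitResult):
    """Variance in the latent factor explained by the structural predictors,
    raw and adjusted for predictor count."""
    spec = fit.spec
    if spec.p < 1:
        raise ModelError("R-square requires at least one structural predictor")
    params = fit.estimates
    explained = float(params.beta @ params.sigma_x @ params.beta)
    v = explained + params.psi
    r2 = explained / v
    k_pred = spec.p - len(spec.zero_paths)
    n = fit.n_used
    if n <= k_pred + 1:
        return r2, float("nan")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k_pred - 1)
    return r2, r2_adj


def fit_indices(fit: FitResult, data: pd.DataFrame) -> FitIndices:
    """Chi-square against the saturated model plus the usual descriptive
    indices (RMSEA, CFI, TLI, SRMR) and information criteria.

    The independence baseline frees every mean and variance and fixes all
    covariances at zero.  SRMR covers the covariance structure only (means
    are saturated in every fitted model).
    """
    spec = fit.spec
    X, _ = _extract(spec, data)
    pdata = lk.pattern_data(X, spec.modeled)
    n = pdata.n
    if pdata.complete:
        S = pdata.cov
        ll_sat = lk.saturated_loglik(pdata)
    else:
        mu_s, S, ll_sat = lk.em_saturated(pdata)
    ll_base = lk.independence_loglik(pdata)
    q = spec.m + spec.p

    chisq = max(2.0 * (ll_sat - fit.loglik), 0.0)
    df = count_df(spec)
    chisq_b = max(2.0 * (ll_sat - ll_base), 0.0)
    df_b = q * (q + 1) // 2 - q

    rmsea = 0.0 if df == 0 else float(np.sqrt(max(chisq - df, 0.0) / (df * n)))
    denom = max(chisq_b - df_b, chisq - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chisq - df, 0.0) / denom
    if df == 0 or df_b == 0 or chisq_b == 0:
        tli = float("nan")
    else:
        ratio_b = chisq_b / df_b
        tli = (ratio_b - chisq / df) / (ratio_b - 1.0)
    _, Sigma_hat = implied_moments(spec, fit.estimates)
    dvar = np.sqrt(np.diag(S))
    resid = (S - Sigma_hat) / np.outer(dvar, dvar)
    iu = np.triu_indices(q)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return FitIndices(chisq=float(chisq), df=int(df), rmsea=rmsea,
                      cfi=float(cfi), tli=float(tli), srmr=srmr,
                      aic=fit.aic, bic=fit.bic)


def likelihood_ratio_test(full: FitResult, nested: FitResult):
    """LRT of a constrained model against the model it nests in.

    Requires identical modeled variables and rows, and the nested model's
    free parameters to be a strict subset (by count) arising from zero or
    equality constraints on the full spec.
    """
    if full.spec.modeled != nested.spec.modeled:
        raise ModelError("models must cover the same modeled variables")
    if full.n_used != nested.n_used:
        raise ModelError("models were fitted on different rows")
    if not (set(nested.spec.zero_paths) >= set(full.spec.zero_paths)
            or (nested.spec.equal_paths and not full.spec.equal_paths)):
        raise ModelError("nested spec is not a constrained version of the full spec")
    df = full.k_free - nested.k_free
    if df < 0:
        raise ModelError("nested model has more free parameters than the full model")
    stat = max(2.0 * (full.loglik - nested.loglik), 0.0)
    if not np.isfinite(stat):
        # identical predictor sets make the exogenous block cancel exactly
        stat = max(2.0 * (full.loglik_cond - nested.loglik_cond), 0.0)
    p = 1.0 if df == 0 else float(scipy.stats.chi2.sf(stat, df))
    if df == 0 and stat <= 1e-8:
        p = 1.0
    return float(stat), int(df), p
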