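"""Lasso-penalized structural paths for MIMIC models.

The penalized objective is

    f(theta) = (-2/n) loglik(theta) + w * sum_p |beta_p|

over the penalized structural coefficients, minimised by proximal gradient:
plain gradient steps on all parameters, soft-thresholding of the penalized
coefficients, and a backtracking line search that guarantees the objective
never increases.  Predictors are standardized to unit sample variance
inside the fit so the penalty is scale-free; estimates are reported on the
standardized and the raw scale.

Model-building fits use complete-case rows by default (the likelihood then
depends on the data only through its sample moments); an opt-in FIML mode
evaluates the pattern-wise likelihood instead.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import likelihood as lk
from .fit import _extract, _full_chain, initial_params
from .model import (ModelSpec, Parameters, ParameterMap, ModelError,
                    implied_moments)


@dataclasses.dataclass
class PenaltyOptions:
    tol: float = 1e-8            # absolute change of the objective
    max_iter: int = 20000
    # "complete_case" (default), "fiml" (exact casewise likelihood) or
    # "pairwise_moments": available-case means and pairwise-complete
    # covariances (with a positive-definite repair) feeding the
    # complete-data objective — consistent under MCAR and as cheap as the
    # complete-data path regardless of predictor count
    missing: str = "complete_case"
    zero_tolerance: float = 1e-3     # on standardized coefficients
    grid_size: int = 40
    grid_ratio: float = 1e-3


@dataclasses.dataclass
class PenaltyGrid:
    """Strictly decreasing, strictly positive penalty weights."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.size == 0 or np.any(w <= 0) or np.any(np.diff(w) >= 0):
            raise ModelError("penalty weights must be positive and strictly decreasing")
        self.weights = w

    @classmethod
    def log_spaced(cls, weight_max: float, size: int = 40,
                   ratio: float = 1e-3) -> "PenaltyGrid":
        return cls(np.geomspace(weight_max, weight_max * ratio, size))


@dataclasses.dataclass
class PenalizedFit:
    spec: ModelSpec
    penalty_weight: float
    estimates: Parameters          # on the standardized-predictor scale
    beta_std: dict[str, float]
    beta_raw: dict[str, float]
    objective_value: float
    loglik: float                  # joint, NaN if the predictor block is singular
    loglik_cond: float
    n_used: int
    n_nonzero: int
    k_base: int                    # free parameters other than penalized paths
    converged: bool
    n_iter: int
    free_vector: np.ndarray | None = None

    @property
    def bic_reg(self) -> float:
        ll = self.loglik if np.isfinite(self.loglik) else self.loglik_cond
        return -2.0 * ll + (self.n_nonzero + self.k_base) * np.log(self.n_used)


@dataclasses.dataclass
class SurvivorSet:
    """Predictors whose standardized penalized path exceeded the zero
    tolerance — the regions 'surviving regularization'."""

    names: tuple[str, ...]
    penalty_weight: float
    family: str | None = None


def _pairwise_moments(X: np.ndarray):
    """Available-case means and pairwise-complete covariances.

    Each covariance entry averages over the rows where both variables are
    observed (centred at the per-column available-case means); the matrix
    is then repaired to positive definite by flooring its eigenvalues.
    Cost is O(n q^2) whatever the missingness pattern structure."""
    obs = ~np.isnan(X)
    cnt_col = obs.sum(axis=0)
    if np.any(cnt_col < 2):
        raise ModelError("a column has fewer than two observed values")
    X0 = np.where(obs, X, 0.0)
    mu = X0.sum(axis=0) / cnt_col
    Xc = np.where(obs, X - mu, 0.0)
    pair_n = obs.T.astype(float) @ obs.astype(float)
    if np.any(pair_n < 2):
        raise ModelError("a variable pair is never jointly observed")
    Sigma = (Xc.T @ Xc) / pair_n
    Sigma = 0.5 * (Sigma + Sigma.T)
    w, V = np.linalg.eigh(Sigma)
    floor = 1e-6 * max(float(w.max()), 1e-12)
    if w.min() < floor:
        Sigma = (V * np.maximum(w, floor)) @ V.T
        Sigma = 0.5 * (Sigma + Sigma.T)
    return mu, Sigma


class _Problem:
    """Smooth part of the penalized objective on standardized predictors."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame,
                 options: PenaltyOptions):
        self.spec = spec
        self.options = options
        mode = options.missing
        if mode not in ("complete_case", "fiml", "pairwise_moments"):
            raise ModelError(f"unknown missing mode {mode!r}")
        work = spec.replace(missing="complete_case" if mode == "complete_case"
                            else "fiml")
        X, rows = _extract(work, data)
        self.n = X.shape[0]
        m, p = spec.m, spec.p
        if self.n < 10:
            raise ModelError("too few usable rows for a penalized fit")
        # standardize predictors to unit sample variance
        xsd = np.nanstd(X[:, m:], axis=0, ddof=0)
        if np.any(~np.isfinite(xsd)) or np.any(xsd <= 0):
            raise ModelError("constant or empty predictor column")
        X = X.copy()
        X[:, m:] = X[:, m:] / xsd
        self.xsd = xsd
        self.rows = rows
        has_nan = bool(np.isnan(X).any())
        self.fiml = mode == "fiml" and has_nan
        if self.fiml:
            self.pdata = lk.pattern_data(X, spec.modeled)
            mu0, Sig0, _ = lk.em_saturated(self.pdata)
            self.mean0, self.cov0 = mu0, Sig0
            self.pmap = ParameterMap(spec, free_x=True)
        else:
            if has_nan:     # pairwise available-case moments, PD-repaired
                mu0, Sig0 = _pairwise_moments(X)
                self.stats = lk.MomentData(
                    self.n, m, tuple(spec.modeled), mu0[:m], mu0[m:],
                    Sig0[:m, :m], Sig0[:m, m:], Sig0[m:, m:])
            else:
                self.stats = lk.MomentData.from_matrix(X, spec.modeled, m)
            self.mean0 = np.concatenate([self.stats.ybar, self.stats.xbar])
            self.cov0 = np.block([[self.stats.Syy, self.stats.Syx],
                                  [self.stats.Syx.T, self.stats.Sxx]])
            self.pmap = ParameterMap(spec, free_x=False)
        self.pen_pos = self.pmap.penalized_positions()
        self.k_base = self.pmap.k - self.pen_pos.size
        self._beta_sl = self.pmap.slices["beta"]
        # box bounds on the log-variance coordinates (two decades around
        # the moment-based start) keep the solver out of the degenerate
        # basin where the latent disturbance collapses to zero
        lo = np.full(self.pmap.k, -np.inf)
        hi = np.full(self.pmap.k, np.inf)
        x_init = self.init_vector()
        span = float(np.log(100.0))
        for name in ("log_theta", "log_psi"):
            sl = self.pmap.slices[name]
            lo[sl] = x_init[sl] - span
            hi[sl] = x_init[sl] + span
        self.lower, self.upper = lo, hi

    def init_vector(self) -> np.ndarray:
        params = initial_params(self.spec, self.mean0, self.cov0)
        x = self.pmap.pack(params)
        x[self.pen_pos] = 0.0
        return x

    def unpack(self, x) -> Parameters:
        if self.fiml:
            return self.pmap.unpack(x)
        return self.pmap.unpack(x, mu_x=self.stats.xbar, sigma_x=self.stats.Sxx)

    def smooth(self, x):
        """(-2/n) loglik and its gradient."""
        params = self.unpack(x)
        try:
            if self.fiml:
                mu, Sigma = implied_moments(self.spec, params)
                ll, gmu, gS = lk.mvn_loglik(mu, Sigma, self.pdata, grad=True)
                d = _full_chain(self.spec, params, gmu, gS, self.pmap)
            else:
                ll, d = lk.conditional_loglik(
                    self.stats, params.nu, params.lam, params.theta,
                    params.psi, params.beta, grad=True)
        except (lk.SingularPatternError, ModelError):
            return np.inf, np.zeros(self.pmap.k)
        g = self.pmap.chain(params, d, x)
        s = -2.0 / self.n
        return s * ll, s * g

    def smooth_value(self, x) -> float:
        params = self.unpack(x)
        try:
            if self.fiml:
                mu, Sigma = implied_moments(self.spec, params)
                ll = lk.mvn_loglik(mu, Sigma, self.pdata)
            else:
                ll = lk.conditional_loglik(
                    self.stats, params.nu, params.lam, params.theta,
                    params.psi, params.beta)
        except (lk.SingularPatternError, ModelError):
            return np.inf
        return -2.0 / self.n * ll

    def logliks(self, x):
        params = self.unpack(x)
        if self.fiml:
            mu, Sigma = implied_moments(self.spec, params)
            ll = lk.mvn_loglik(mu, Sigma, self.pdata)
            return ll, float("nan")
        ll_cond = lk.conditional_loglik(self.stats, params.nu, params.lam,
                                        params.theta, params.psi, params.beta)
        return ll_cond + lk.xblock_loglik(self.n, self.stats.Sxx), ll_cond

    def beta_std(self, params: Parameters) -> np.ndarray:
        sd_g = np.sqrt(params.latent_variance)
        sd_x = np.sqrt(np.diag(params.sigma_x))
        return params.beta * sd_x / sd_g


def _soft(v, t):
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _pen_term(weight, l1):
    # 0 * inf guard for the all-zero null fit at weight = infinity
    return 0.0 if l1 == 0.0 else weight * l1


def _prox_solve(problem: _Problem, weight: float, x0: np.ndarray,
                options: PenaltyOptions, history: list | None = None):
    """Accelerated proximal gradient (FISTA) with backtracking and adaptive
    restart.  Restarting whenever the extrapolated step would raise the
    objective keeps the sequence of accepted objective values
    non-increasing."""
    pen = problem.pen_pos
    x = np.clip(x0, problem.lower, problem.upper)
    if not np.isfinite(weight):
        x[pen] = 0.0
    obj = problem.smooth_value(x) + _pen_term(weight, np.abs(x[pen]).sum())
    if history is not None:
        history.append(obj)
    y = x.copy()
    t = 1.0
    step = 1.0
    converged = False
    it = 0
    while it < options.max_iter:
        it += 1
        f_y, g_y = problem.smooth(y)
        if not np.isfinite(f_y):
            y = x.copy()
            t = 1.0
            f_y, g_y = problem.smooth(y)
        while True:
            z = y - step * g_y
            z[pen] = _soft(z[pen], step * weight)
            np.clip(z, problem.lower, problem.upper, out=z)
            fz = problem.smooth_value(z)
            dz = z - y
            quad = f_y + g_y @ dz + (dz @ dz) / (2.0 * step)
            if fz <= quad + 1e-12:
                break
            step *= 0.5
            if step < 1e-15:
                break
        if step < 1e-15:
            break
        new_obj = fz + _pen_term(weight, np.abs(z[pen]).sum())
        if new_obj > obj + 1e-12:
            # momentum overshoot: drop acceleration and retry from x
            y = x.copy()
            t = 1.0
            continue
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = z + ((t - 1.0) / t_new) * (z - x)
        done = abs(obj - new_obj) < options.tol
        x = z
        obj = new_obj
        t = t_new
        if history is not None:
            history.append(obj)
        if done:
            converged = True
            break
        step = min(step * 1.2, 1e6)
    return x, obj, converged, it


def _finish(problem: _Problem, weight, x, obj, converged, n_iter) -> PenalizedFit:
    spec = problem.spec
    params = problem.unpack(x)
    bstd = problem.beta_std(params)
    pen_mask = np.array([nm in set(spec.penalized) for nm in spec.predictors])
    nz = int((np.abs(bstd) > problem.options.zero_tolerance)[pen_mask].sum())
    ll, ll_cond = problem.logliks(x)
    beta_raw = params.beta / problem.xsd
    return PenalizedFit(
        spec=spec, penalty_weight=float(weight), estimates=params,
        beta_std=dict(zip(spec.predictors, bstd)),
        beta_raw=dict(zip(spec.predictors, beta_raw)),
        objective_value=float(obj), loglik=float(ll), loglik_cond=float(ll_cond),
        n_used=problem.n, n_nonzero=nz, k_base=problem.k_base,
        converged=converged, n_iter=n_iter, free_vector=x.copy())


def fit_penalized(spec: ModelSpec, data: pd.DataFrame, penalty_weight: float,
                  options: PenaltyOptions | None = None,
                  warm: PenalizedFit | None = None,
                  _problem: _Problem | None = None) -> PenalizedFit:
    """Minimise the lasso-penalized negative log-likelihood at one weight."""
    if penalty_weight < 0:
        raise ModelError("penalty weight must be non-negative")
    options = options or PenaltyOptions()
    problem = _problem or _Problem(spec, data, options)
    x0 = warm.free_vector if warm is not None else problem.init_vector()
    x, obj, conv, it = _prox_solve(problem, penalty_weight, x0, options)
    return _finish(problem, penalty_weight, x, obj, conv, it)


def weight_max(spec: ModelSpec, data: pd.DataFrame,
               options: PenaltyOptions | None = None,
               _problem: _Problem | None = None) -> float:
    """Smallest weight that shrinks every penalized path to zero: the
    infinity-norm of the smooth gradient over penalized coordinates at the
    null-path solution (all penalized beta = 0)."""
    options = options or PenaltyOptions()
    problem = _problem or _Problem(spec, data, options)
    wmax, _ = _weight_max_and_null(problem, options)
    return wmax


def _weight_max_and_null(problem: _Problem, options: PenaltyOptions):
    x, _, _, _ = _prox_solve(problem, np.inf, problem.init_vector(), options)
    _, g = problem.smooth(x)
    wmax = float(np.max(np.abs(g[problem.pen_pos])))
    return wmax * (1.0 + 1e-4), x


def fit_path(spec: ModelSpec, data: pd.DataFrame,
             grid: PenaltyGrid | None = None,
             options: PenaltyOptions | None = None) -> list[PenalizedFit]:
    """Penalty path in decreasing-weight order with warm starts.

    Failures at individual weights are recorded (``converged = False``) and
    the path continues from the last successful solution.
    """
    options = options or PenaltyOptions()
    problem = _Problem(spec, data, options)
    wmax, x = _weight_max_and_null(problem, options)
    if grid is None:
        grid = PenaltyGrid.log_spaced(wmax, options.grid_size,
                                      options.grid_ratio)
    fits = []
    for w in grid.weights:
        x_new, obj, conv, it = _prox_solve(problem, float(w), x, options)
        fits.append(_finish(problem, w, x_new, obj, conv, it))
        if np.isfinite(obj):
            x = x_new
    return fits


def select_penalty(path: list[PenalizedFit], criterion: str = "bic") -> PenalizedFit:
    """Pick the penalty weight by an information criterion that counts the
    nonzero penalized paths as free parameters; ties go to the sparser
    (larger-weight) fit."""
    if not path:
        raise ModelError("empty penalty path")
    usable = [f for f in path if f.converged]
    if not usable:
        raise ModelError("no converged fit in the penalty path")
    if criterion == "bic":
        scores = [f.bic_reg for f in usable]
    elif criterion == "aic":
        ll = [f.loglik if np.isfinite(f.loglik) else f.loglik_cond for f in usable]
        scores = [-2.0 * l + 2.0 * (f.n_nonzero + f.k_base)
                  for l, f in zip(ll, usable)]
    else:
        raise ModelError(f"unknown criterion {criterion!r}")
    order = sorted(range(len(usable)),
                   key=lambda i: (scores[i], -usable[i].penalty_weight))
    return usable[order[0]]


def survivors(fit: PenalizedFit, zero_tolerance: float = 1e-3,
              family: str | None = None) -> SurvivorSet:
    """Penalized paths with |standardized beta| above the zero tolerance."""
    if not fit.converged:
        raise ModelError("survivor extraction requires a converged fit")
    names = tuple(n for n in fit.spec.penalized
                  if abs(fit.beta_std[n]) > zero_tolerance)
    return SurvivorSet(names=names, penalty_weight=fit.penalty_weight,
                       family=family)
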