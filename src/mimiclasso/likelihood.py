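"""Gaussian likelihood machinery for latent-factor MIMIC models.

Everything in this module works on the joint multivariate-normal
distribution of the modeled variables (cognitive task indicators first,
brain-metric predictors after).  Missing cells are handled with full
information maximum likelihood (FIML): each row contributes the log density
of its observed subvector under the marginal normal obtained by subsetting
the implied mean and covariance to the row's observed pattern.

Rows are grouped by missingness pattern and each pattern is summarised by
its sufficient statistics (count, mean, scatter), so likelihood and
gradient evaluations cost O(patterns * k^3) independent of the row count.
Patterns with the same number of observed variables are stacked and
evaluated with batched linear algebra.
"""

from __future__ import annotations

import dataclasses

import numpy as np

LOG2PI = float(np.log(2.0 * np.pi))


class SingularPatternError(np.linalg.LinAlgError):
    """Implied covariance is singular on some observed-variable pattern."""


@dataclasses.dataclass
class PatternBucket:
    """Stacked sufficient statistics for patterns with ``k`` observed vars.

    ``idx`` holds the observed column indices (P, k), ``midx`` the missing
    ones (P, q-k); ``mean`` and ``scatter`` are the per-pattern sample mean
    and ML (divide-by-n) covariance of the observed subvectors.
    """

    idx: np.ndarray
    midx: np.ndarray
    n: np.ndarray
    mean: np.ndarray
    scatter: np.ndarray

    @property
    def k(self) -> int:
        return self.idx.shape[1]


@dataclasses.dataclass
class PatternData:
    """Missingness-pattern summary of a data matrix."""

    names: tuple[str, ...]
    n: int
    q: int
    buckets: list[PatternBucket]
    complete: bool
    mean: np.ndarray | None = None   # sample mean when complete
    cov: np.ndarray | None = None    # ML sample covariance when complete


def pattern_data(X: np.ndarray, names) -> PatternData:
    """Group the rows of ``X`` (NaN = missing) by missingness pattern.

    Rows with no observed value at all are rejected: they carry no
    likelihood information and would silently change ``n``.
    """
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        bad = int(np.flatnonzero(~obs.any(axis=1))[0])
        raise ValueError(f"row {bad} has no observed modeled variable")

    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    per_k: dict[int, list[tuple[np.ndarray, np.ndarray, int, np.ndarray, np.ndarray]]] = {}
    for pid in range(patterns.shape[0]):
        pat = patterns[pid]
        rows = np.flatnonzero(inverse == pid)
        cols = np.flatnonzero(pat)
        mcols = np.flatnonzero(~pat)
        Xp = X[np.ix_(rows, cols)]
        np_ = rows.size
        mean = Xp.mean(axis=0)
        dev = Xp - mean
        scatter = dev.T @ dev / np_
        per_k.setdefault(cols.size, []).append((cols, mcols, np_, mean, scatter))

    buckets = []
    for k in sorted(per_k):
        entries = per_k[k]
        buckets.append(PatternBucket(
            idx=np.array([e[0] for e in entries], dtype=np.intp),
            midx=np.array([e[1] for e in entries], dtype=np.intp),
            n=np.array([e[2] for e in entries], dtype=float),
            mean=np.array([e[3] for e in entries]),
            scatter=np.array([e[4] for e in entries]),
        ))

    complete = len(buckets) == 1 and buckets[0].k == q and buckets[0].idx.shape[0] == 1
    mean = cov = None
    if complete:
        mean = buckets[0].mean[0]
        cov = buckets[0].scatter[0]
    return PatternData(tuple(names), n, q, buckets, complete, mean, cov)


def mvn_loglik(mu: np.ndarray, Sigma: np.ndarray, pdata: PatternData,
               grad: bool = False):
    """FIML log-likelihood (and gradient w.r.t. ``mu``/``Sigma``).

    The gradient with respect to ``Sigma`` is returned as a full symmetric
    matrix ``G`` such that the directional derivative along a symmetric
    perturbation ``dS`` is ``sum(G * dS)``.
    """
    q = pdata.q
    ll = 0.0
    gmu = np.zeros(q) if grad else None
    gS = np.zeros((q, q)) if grad else None
    for b in pdata.buckets:
        k = b.k
        Sig = Sigma[b.idx[:, :, None], b.idx[:, None, :]]
        try:
            L = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError as exc:
            bad = _first_singular(Sig, b, pdata.names)
            raise SingularPatternError(
                f"singular implied covariance on observed pattern {bad}"
            ) from exc
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
        d = b.mean - mu[b.idx]
        St = b.scatter + d[:, :, None] * d[:, None, :]
        eye = np.broadcast_to(np.eye(k), Sig.shape)
        Si = np.linalg.solve(Sig, eye)
        tr = np.einsum('pij,pji->p', Si, St)
        ll += float((-0.5 * b.n * (k * LOG2PI + logdet + tr)).sum())
        if grad:
            gmu_c = b.n[:, None] * np.einsum('pij,pj->pi', Si, d)
            np.add.at(gmu, b.idx, gmu_c)
            B = Si @ St @ Si
            gS_c = 0.5 * b.n[:, None, None] * (B - Si)
            np.add.at(gS, (b.idx[:, :, None], b.idx[:, None, :]), gS_c)
    if grad:
        return ll, gmu, gS
    return ll


def _first_singular(Sig_stack, bucket, names):
    for p in range(Sig_stack.shape[0]):
        try:
            np.linalg.cholesky(Sig_stack[p])
        except np.linalg.LinAlgError:
            return tuple(names[j] for j in bucket.idx[p])
    return "<unidentified>"


def em_saturated(pdata: PatternData, max_iter: int = 500, tol: float = 1e-9,
                 ridge: float = 1e-10):
    """ML mean and covariance of the unstructured (saturated) normal.

    Complete data reduces to the sample moments; otherwise the standard EM
    recursion for a Gaussian with arbitrary missingness patterns is run on
    the pattern sufficient statistics until the per-observation
    log-likelihood stabilises.  Returns ``(mu, Sigma, loglik)``.
    """
    if pdata.complete:
        mu, Sigma = pdata.mean.copy(), pdata.cov.copy()
        return mu, Sigma, mvn_loglik(mu, Sigma, pdata)

    q, n = pdata.q, pdata.n
    # available-case initialisation: observed means, diagonal covariance
    cnt = np.zeros(q)
    s1 = np.zeros(q)
    s2 = np.zeros(q)
    for b in pdata.buckets:
        np.add.at(cnt, b.idx, np.broadcast_to(b.n[:, None], b.idx.shape))
        np.add.at(s1, b.idx, b.n[:, None] * b.mean)
        diag = np.diagonal(b.scatter, axis1=1, axis2=2) + b.mean ** 2
        np.add.at(s2, b.idx, b.n[:, None] * diag)
    mu = s1 / np.maximum(cnt, 1.0)
    var = np.maximum(s2 / np.maximum(cnt, 1.0) - mu ** 2, 1e-8)
    Sigma = np.diag(var)

    prev = -np.inf
    for _ in range(max_iter):
        T1 = np.zeros(q)
        T2 = np.zeros((q, q))
        for b in pdata.buckets:
            Soo = Sigma[b.idx[:, :, None], b.idx[:, None, :]]
            d = b.mean - mu[b.idx]
            M2 = b.n[:, None, None] * (b.scatter + b.mean[:, :, None] * b.mean[:, None, :])
            np.add.at(T1, b.idx, b.n[:, None] * b.mean)
            np.add.at(T2, (b.idx[:, :, None], b.idx[:, None, :]), M2)
            if b.midx.shape[1] == 0:
                continue
            Smo = Sigma[b.midx[:, :, None], b.idx[:, None, :]]
            Smm = Sigma[b.midx[:, :, None], b.midx[:, None, :]]
            B = np.linalg.solve(Soo, Smo.transpose(0, 2, 1)).transpose(0, 2, 1)
            mhat = mu[b.midx] + np.einsum('pij,pj->pi', B, d)
            C = Smm - B @ Smo.transpose(0, 2, 1)
            np.add.at(T1, b.midx, b.n[:, None] * mhat)
            cross = b.n[:, None, None] * (
                mhat[:, :, None] * b.mean[:, None, :] + B @ b.scatter)
            np.add.at(T2, (b.midx[:, :, None], b.idx[:, None, :]), cross)
            np.add.at(T2, (b.idx[:, :, None], b.midx[:, None, :]),
                      cross.transpose(0, 2, 1))
            mm = b.n[:, None, None] * (
                B @ b.scatter @ B.transpose(0, 2, 1)
                + mhat[:, :, None] * mhat[:, None, :] + C)
            np.add.at(T2, (b.midx[:, :, None], b.midx[:, None, :]), mm)
        mu = T1 / n
        Sigma = T2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T) + ridge * np.eye(q)
        ll = mvn_loglik(mu, Sigma, pdata)
        if abs(ll - prev) < tol * (1.0 + abs(ll)):
            prev = ll
            break
        prev = ll
    return mu, Sigma, prev


def saturated_loglik(pdata: PatternData) -> float:
    """Log-likelihood of the saturated (unstructured) normal model."""
    if pdata.complete:
        sign, logdet = np.linalg.slogdet(pdata.cov)
        if sign <= 0:
            return float("nan")
        return -0.5 * pdata.n * (pdata.q * LOG2PI + logdet + pdata.q)
    return em_saturated(pdata)[2]


def independence_loglik(pdata: PatternData) -> float:
    """Log-likelihood of the independence baseline (free means/variances,
    zero covariances); closed form because the likelihood separates by
    column under independence."""
    q = pdata.q
    cnt = np.zeros(q)
    s1 = np.zeros(q)
    s2 = np.zeros(q)
    for b in pdata.buckets:
        np.add.at(cnt, b.idx, np.broadcast_to(b.n[:, None], b.idx.shape))
        np.add.at(s1, b.idx, b.n[:, None] * b.mean)
        diag = np.diagonal(b.scatter, axis1=1, axis2=2) + b.mean ** 2
        np.add.at(s2, b.idx, b.n[:, None] * diag)
    mu = s1 / cnt
    var = np.maximum(s2 / cnt - mu ** 2, 1e-300)
    return float((-0.5 * cnt * (LOG2PI + np.log(var) + 1.0)).sum())


# ---------------------------------------------------------------------------
# conditional (complete-data) engine
#
# With complete data the joint likelihood factorises into a saturated
# marginal for the exogenous predictors (maximised by the sample moments)
# and a conditional likelihood for the indicators given the predictors that
# involves only (nu, lambda, theta, beta, psi).  Fitting then only needs the
# sample moments, so evaluations are O(1) in the row count.
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MomentData:
    """Complete-data sufficient statistics, partitioned indicator/predictor."""

    n: int
    m: int
    names: tuple[str, ...]
    ybar: np.ndarray
    xbar: np.ndarray
    Syy: np.ndarray
    Syx: np.ndarray
    Sxx: np.ndarray

    @classmethod
    def from_matrix(cls, X: np.ndarray, names, m: int) -> "MomentData":
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        mean = X.mean(axis=0)
        dev = X - mean
        S = dev.T @ dev / n
        return cls(n, m, tuple(names), mean[:m], mean[m:],
                   S[:m, :m], S[:m, m:], S[m:, m:])


def conditional_loglik(stats: MomentData, nu, lam, theta, psi, beta,
                       grad: bool = False):
    """Log-likelihood of indicators given predictors, from sample moments.

    The conditional law is N(nu + lam * beta'x, psi*lam lam' + diag(theta)).
    Returns the log-likelihood, plus (when ``grad``) derivatives with
    respect to nu, lam, theta, psi and beta.
    """
    n, m = stats.n, stats.m
    lam = np.asarray(lam, float)
    theta = np.asarray(theta, float)
    beta = np.asarray(beta, float)
    Omega = psi * np.outer(lam, lam) + np.diag(theta)
    try:
        L = np.linalg.cholesky(Omega)
    except np.linalg.LinAlgError as exc:
        raise SingularPatternError("singular conditional indicator covariance") from exc
    logdet = 2.0 * np.log(np.diag(L)).sum()
    W = np.linalg.inv(Omega)

    c = stats.Sxx @ beta                      # Cov(x) beta
    vb = float(beta @ c)                      # beta' Sxx beta
    sxy_b = stats.Syx @ beta                  # Cov(y, beta'x)
    delta = stats.ybar - nu - lam * float(beta @ stats.xbar)
    M = (stats.Syy - np.outer(sxy_b, lam) - np.outer(lam, sxy_b)
         + vb * np.outer(lam, lam) + np.outer(delta, delta))
    ll = -0.5 * n * (m * LOG2PI + logdet + float(np.einsum('ij,ji->', W, M)))
    if not grad:
        return ll

    Wlam = W @ lam
    Wdelta = W @ delta
    lWl = float(lam @ Wlam)
    bx = float(beta @ stats.xbar)
    # d/d(param) of logdet + tr(W M), then scale by -n/2
    d_nu = -2.0 * Wdelta
    d_lam = (2.0 * psi * Wlam
             - 2.0 * (W @ sxy_b) + 2.0 * vb * Wlam - 2.0 * bx * Wdelta)
    d_theta = np.diag(W) - np.einsum('ij,jk,ki->i', W, M, W)
    d_psi = lWl - float(Wlam @ M @ Wlam)
    WMW = W @ M @ W
    d_lam -= 2.0 * psi * (WMW @ lam)
    # M-part of d_lam computed with W fixed above; the Omega-dependence of
    # tr(W M) on lam enters through W:
    #   d tr(WM)/dOmega = -W M W, dOmega/dlam_j = psi (e_j lam' + lam e_j')
    d_beta = (-2.0 * (stats.Syx.T @ Wlam) + 2.0 * lWl * c
              - 2.0 * float(lam @ Wdelta) * stats.xbar)
    scale = -0.5 * n
    return ll, {
        'nu': scale * d_nu,
        'lam': scale * d_lam,
        'theta': scale * d_theta,
        'psi': scale * d_psi,
        'beta': scale * d_beta,
    }


def xblock_loglik(n: int, Sxx: np.ndarray) -> float:
    """Log-likelihood of the saturated exogenous block at its ML solution
    (the sample moments).  NaN if the sample covariance is singular."""
    p = Sxx.shape[0]
    if p == 0:
        return 0.0
    sign, logdet = np.linalg.slogdet(Sxx)
    if sign <= 0 or not np.isfinite(logdet):
        return float("nan")
    return -0.5 * n * (p * LOG2PI + logdet + p)
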