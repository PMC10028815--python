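"""FIML likelihood engine: closed-form oracles and gradient correctness."""

import numpy as np
import pytest
import scipy.stats

from mimiclasso import likelihood as lk
from mimiclasso.fit import _full_chain, loglik_fiml
from mimiclasso.model import Parameters, ParameterMap, implied_moments, mimic_spec

import pandas as pd


@pytest.fixture(scope="module")
def small_model():
    spec = mimic_spec(tuple("abcde"), ("x1", "x2", "x3"))
    params = Parameters(lam=[1, .8, .7, .6, .5], nu=np.zeros(5),
                        theta=np.full(5, .5), beta=[.3, -.2, .1], psi=.8,
                        mu_x=np.array([0.1, -0.2, 0.0]),
                        sigma_x=np.eye(3) + 0.2)
    return spec, params


def _draw(spec, params, n, missing, seed):
    rng = np.random.default_rng(seed)
    mu, Sigma = implied_moments(spec, params)
    X = rng.multivariate_normal(mu, Sigma, size=n)
    if missing:
        mask = rng.random(X.shape) < missing
        # never a fully-missing row
        mask[mask.all(axis=1), 0] = False
        X[mask] = np.nan
    return X


def test_fiml_equals_rowwise_marginals(small_model):
    """Pattern-grouped evaluation equals the naive row-by-row sum of
    observed-subvector normal densities."""
    spec, params = small_model
    X = _draw(spec, params, 60, 0.3, seed=1)
    mu, Sigma = implied_moments(spec, params)
    pdata = lk.pattern_data(X, spec.modeled)
    ll = lk.mvn_loglik(mu, Sigma, pdata)
    ll_ref = sum(
        scipy.stats.multivariate_normal.logpdf(
            row[~np.isnan(row)], mu[~np.isnan(row)],
            Sigma[np.ix_(~np.isnan(row), ~np.isnan(row))])
        for row in X)
    assert ll == pytest.approx(ll_ref, rel=1e-12)


def test_fiml_complete_equals_complete_loglik(small_model):
    """With no missing cells FIML is exactly the complete-data likelihood."""
    spec, params = small_model
    X = _draw(spec, params, 80, 0.0, seed=2)
    df = pd.DataFrame(X, columns=spec.modeled)
    ll_fiml = loglik_fiml(spec, params, df)
    mu, Sigma = implied_moments(spec, params)
    ll_ref = scipy.stats.multivariate_normal.logpdf(X, mu, Sigma).sum()
    assert ll_fiml == pytest.approx(ll_ref, rel=1e-14)


def test_single_missing_cell_marginalization_oracle(small_model):
    """One row, one missing cell: the contribution equals the closed-form
    marginal normal with that dimension deleted."""
    spec, params = small_model
    mu, Sigma = implied_moments(spec, params)
    row = np.arange(8, dtype=float) / 7.0
    row[3] = np.nan
    pdata = lk.pattern_data(row[None, :], spec.modeled)
    keep = [i for i in range(8) if i != 3]
    expect = scipy.stats.multivariate_normal.logpdf(
        row[keep], mu[keep], Sigma[np.ix_(keep, keep)])
    assert lk.mvn_loglik(mu, Sigma, pdata) == pytest.approx(expect, rel=1e-12)


def test_gaussian_mle_identity():
    """Univariate model at its own ML solution: ll = -n/2 (log(2 pi s2)+1)."""
    rng = np.random.default_rng(3)
    x = rng.normal(2.0, 1.5, size=200)
    pdata = lk.pattern_data(x[:, None], ("v",))
    mu = np.array([x.mean()])
    s2 = np.array([[x.var()]])
    expect = -len(x) / 2 * (np.log(2 * np.pi * s2[0, 0]) + 1.0)
    assert lk.mvn_loglik(mu, s2, pdata) == pytest.approx(expect, rel=1e-12)


def test_singular_pattern_rejected(small_model):
    spec, params = small_model
    X = _draw(spec, params, 10, 0.0, seed=4)
    pdata = lk.pattern_data(X, spec.modeled)
    mu, Sigma = implied_moments(spec, params)
    bad = Sigma.copy()
    bad[0, :] = bad[1, :]
    bad[:, 0] = bad[:, 1]
    with pytest.raises(lk.SingularPatternError):
        lk.mvn_loglik(mu, bad, pdata)


def test_all_missing_row_rejected():
    X = np.array([[1.0, 2.0], [np.nan, np.nan]])
    with pytest.raises(ValueError, match="row 1"):
        lk.pattern_data(X, ("a", "b"))


def test_fiml_gradient_matches_finite_differences(small_model):
    spec, params = small_model
    X = _draw(spec, params, 120, 0.25, seed=5)
    pdata = lk.pattern_data(X, spec.modeled)
    pmap = ParameterMap(spec, free_x=True)
    x0 = pmap.pack(params)

    def f(x):
        p = pmap.unpack(x)
        mu, Sigma = implied_moments(spec, p)
        return lk.mvn_loglik(mu, Sigma, pdata)

    p0 = pmap.unpack(x0)
    mu, Sigma = implied_moments(spec, p0)
    ll0, gmu, gS = lk.mvn_loglik(mu, Sigma, pdata, grad=True)
    g = pmap.chain(p0, _full_chain(spec, p0, gmu, gS, pmap), x0)
    eps = 1e-6
    num = np.array([(f(x0 + eps * np.eye(x0.size)[k]) - ll0) / eps
                    for k in range(x0.size)])
    np.testing.assert_allclose(num, g, rtol=2e-3, atol=2e-3)


def test_conditional_gradient_matches_finite_differences(small_model):
    spec, params = small_model
    X = _draw(spec, params, 300, 0.0, seed=6)
    stats = lk.MomentData.from_matrix(X, spec.modeled, 5)
    args = (params.nu, params.lam, params.theta, params.psi, params.beta)
    ll0, d = lk.conditional_loglik(stats, *args, grad=True)
    eps = 1e-6

    def ll(nu=args[0], lam=args[1], th=args[2], ps=args[3], be=args[4]):
        return lk.conditional_loglik(stats, nu, lam, th, ps, be)

    for name, vec, grad in (("nu", args[0], d["nu"]), ("lam", args[1], d["lam"]),
                            ("theta", args[2], d["theta"]),
                            ("beta", args[4], d["beta"])):
        for k in range(len(vec)):
            v2 = np.array(vec, float)
            v2[k] += eps
            num = (ll(**{name if name != "lam" else "lam": v2}) - ll0) / eps \
                if name in ("nu", "lam") else \
                (ll(th=v2) - ll0) / eps if name == "theta" else \
                (ll(be=v2) - ll0) / eps
            assert num == pytest.approx(grad[k], rel=5e-3, abs=5e-3)
    assert (ll(ps=args[3] + eps) - ll0) / eps == pytest.approx(
        d["psi"], rel=5e-3, abs=5e-3)


def test_em_saturated_complete_is_sample_moments(small_model):
    spec, params = small_model
    X = _draw(spec, params, 100, 0.0, seed=7)
    pdata = lk.pattern_data(X, spec.modeled)
    mu, Sigma, ll = lk.em_saturated(pdata)
    np.testing.assert_allclose(mu, X.mean(axis=0))
    np.testing.assert_allclose(Sigma, np.cov(X, rowvar=False, ddof=0),
                               atol=1e-10)


def test_em_saturated_is_stationary(small_model):
    """EM solution should not be improved by local perturbations."""
    spec, params = small_model
    X = _draw(spec, params, 250, 0.3, seed=8)
    pdata = lk.pattern_data(X, spec.modeled)
    mu, Sigma, ll = lk.em_saturated(pdata, max_iter=3000, tol=1e-12)
    rng = np.random.default_rng(0)
    for _ in range(5):
        dmu = rng.normal(0, 0.01, mu.shape)
        A = rng.normal(0, 0.005, Sigma.shape)
        assert lk.mvn_loglik(mu + dmu, Sigma + A @ A.T, pdata) <= ll + 1e-6


def test_independence_loglik_matches_columnwise(small_model):
    spec, params = small_model
    X = _draw(spec, params, 90, 0.2, seed=9)
    pdata = lk.pattern_data(X, spec.modeled)
    ll = lk.independence_loglik(pdata)
    ll_ref = 0.0
    for j in range(X.shape[1]):
        col = X[:, j]
        col = col[~np.isnan(col)]
        ll_ref += scipy.stats.norm.logpdf(col, col.mean(),
                                          col.std(ddof=0)).sum()
    assert ll == pytest.approx(ll_ref, rel=1e-12)
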