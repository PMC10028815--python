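"""Free ML fitting: recovery, identification, indices, tests and R-square."""

import numpy as np
import pandas as pd
import pytest

from mimiclasso import cohort as ch
from mimiclasso.fit import (FitOptions, fit_free, fit_indices,
                            likelihood_ratio_test, loglik_fiml,
                            rsquare_latent)
from mimiclasso.model import (ModelError, Parameters, implied_moments,
                              measurement_spec, mimic_spec,
                              IDENT_LATENT_VARIANCE)

OPT = FitOptions(se=False)


def _exact_moment_data(spec, params, n, seed=0):
    """Draw n rows, then affinely transform them so the SAMPLE moments equal
    the implied moments exactly — the fitted model then fits perfectly."""
    rng = np.random.default_rng(seed)
    mu, Sigma = implied_moments(spec, params)
    Z = rng.standard_normal((n, mu.size))
    Z = Z - Z.mean(axis=0)
    Sz = np.cov(Z, rowvar=False, ddof=0)
    W = np.linalg.cholesky(Sigma) @ np.linalg.inv(np.linalg.cholesky(Sz))
    X = Z @ W.T + mu
    return pd.DataFrame(X, columns=spec.modeled)


@pytest.fixture(scope="module")
def cfa_data():
    spec = measurement_spec(tuple("abcde"))
    params = Parameters(lam=[1, .9, .75, .6, .55], nu=np.zeros(5),
                        theta=[.5, .6, .7, .8, .9], beta=[], psi=1.2,
                        mu_x=[], sigma_x=np.empty((0, 0)))
    return spec, params


def test_perfect_fit_chisq_zero(cfa_data):
    spec, params = cfa_data
    df = _exact_moment_data(spec, params, 500)
    fit = fit_free(spec, df, OPT)
    assert fit.converged
    fi = fit_indices(fit, df)
    assert fi.chisq < 1e-4
    assert fi.srmr < 1e-4
    assert fi.cfi == pytest.approx(1.0)
    assert fi.rmsea == pytest.approx(0.0)


def test_parameter_recovery(tiny_partial, tiny_spec):
    """Loadings and structural paths recovered within +-0.05 at n = 4000."""
    design, table, _ = tiny_partial
    fit = fit_free(tiny_spec, table, OPT)
    assert fit.converged
    for name, lam in zip(design.indicators, design.loadings):
        assert fit.standardized["lam"][name] == pytest.approx(lam, abs=0.05)
    for name in design.predictors:
        assert fit.standardized["beta"][name] == pytest.approx(
            design.true_beta[name], abs=0.05)


def test_fiml_recovery_under_mcar():
    """FIML estimates stay within 3 SE-sized bands of the generating values
    under 20% cell-wise MCAR."""
    d = ch.make_design("partial", 3000, 0.5, seed=31, preset="tiny",
                       n_signal_per_tissue=2, missing_rate=0.2)
    table, _ = ch.generate_cohort(d)
    signal = tuple(n for n, v in d.true_beta.items() if v > 0)
    noise = tuple(n for n, v in d.true_beta.items() if v == 0)[:2]
    spec = mimic_spec(d.indicators, signal + noise)
    fit = fit_free(spec, table, OPT)
    assert fit.converged
    for name in spec.predictors:
        assert fit.standardized["beta"][name] == pytest.approx(
            d.true_beta[name], abs=0.06)


def test_chisq_invariant_to_identification(cfa_data):
    spec, params = cfa_data
    rng_df = _exact_moment_data(spec, params, 400, seed=3)
    noisy = rng_df + np.random.default_rng(1).normal(
        0, 0.3, rng_df.shape)           # break the perfect fit
    f1 = fit_free(spec, noisy, OPT)
    f2 = fit_free(spec.replace(identification=IDENT_LATENT_VARIANCE),
                  noisy, OPT)
    c1 = fit_indices(f1, noisy).chisq
    c2 = fit_indices(f2, noisy).chisq
    assert c1 == pytest.approx(c2, abs=1e-4)
    assert f1.k_free == f2.k_free


def test_row_order_invariance(tiny_partial, tiny_spec):
    _, table, _ = tiny_partial
    sub = table.iloc[:800]
    fit1 = fit_free(tiny_spec, sub, OPT)
    shuffled = sub.sample(frac=1.0, random_state=7).reset_index(drop=True)
    fit2 = fit_free(tiny_spec, shuffled, OPT)
    assert fit1.loglik == pytest.approx(fit2.loglik, rel=1e-9)
    np.testing.assert_allclose(fit1.estimates.beta, fit2.estimates.beta,
                               atol=1e-5)


def test_standardized_zero_beta():
    d = ch.make_design("partial", 1500, 0.5, seed=32, preset="tiny")
    for n in d.true_beta:
        d.true_beta[n] = 0.0
    table, _ = ch.generate_cohort(d)
    spec = mimic_spec(d.indicators, d.predictors[:3],
                      zero_paths=d.predictors[:3])
    fit = fit_free(spec, table, OPT)
    assert all(abs(v) < 1e-12 for v in fit.standardized["beta"].values())


def test_standardized_single_predictor_correlation_oracle():
    """With one predictor, the standardized path equals the latent-observed
    correlation: check against the generating latent scores at scale."""
    d = ch.make_design("partial", 100_000, 0.4, seed=33, preset="tiny",
                       n_signal_per_tissue=1)
    table, truth = ch.generate_cohort(d)
    name = [n for n, v in d.true_beta.items() if v > 0][0]
    spec = mimic_spec(d.indicators, (name,))
    fit = fit_free(spec, table, OPT)
    r = np.corrcoef(table[name], truth.latent_scores)[0, 1]
    assert fit.standardized["beta"][name] == pytest.approx(r, abs=0.01)


def test_fit_indices_hand_arithmetic_oracle(tiny_partial):
    """All six indices reproduced from scratch from the two likelihoods and
    the residual matrix."""
    design, table, _ = tiny_partial
    sub = table.iloc[:1500]
    spec = mimic_spec(design.indicators, design.predictors[:2])
    fit = fit_free(spec, sub, OPT)
    fi = fit_indices(fit, sub)

    cols = list(spec.modeled)
    X = sub[cols].to_numpy()
    n, q = X.shape
    S = np.cov(X, rowvar=False, ddof=0)
    sign, logdet = np.linalg.slogdet(S)
    ll_sat = -n / 2 * (q * np.log(2 * np.pi) + logdet + q)
    var = X.var(axis=0)
    ll_base = sum(-n / 2 * (np.log(2 * np.pi * v) + 1.0) for v in var)
    chisq = 2 * (ll_sat - fit.loglik)
    df = 7 * 8 // 2 - (4 + 5 + 1 + 2 + 3)
    chisq_b = 2 * (ll_sat - ll_base)
    df_b = q * (q + 1) // 2 - q
    assert fi.chisq == pytest.approx(chisq, abs=1e-6)
    assert fi.df == df
    assert fi.rmsea == pytest.approx(
        np.sqrt(max(chisq - df, 0) / (df * n)), abs=1e-6)
    assert fi.cfi == pytest.approx(
        1 - max(chisq - df, 0) / max(chisq_b - df_b, chisq - df, 0), abs=1e-6)
    assert fi.tli == pytest.approx(
        ((chisq_b / df_b) - (chisq / df)) / ((chisq_b / df_b) - 1), abs=1e-6)
    _, Sigma_hat = implied_moments(spec, fit.estimates)
    dv = np.sqrt(np.diag(S))
    resid = (S - Sigma_hat) / np.outer(dv, dv)
    iu = np.triu_indices(q)
    assert fi.srmr == pytest.approx(np.sqrt(np.mean(resid[iu] ** 2)), abs=1e-9)
    assert fi.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k_free)
    assert fi.bic == pytest.approx(-2 * fit.loglik + fit.k_free * np.log(n))


def test_aic_difference_identity(tiny_partial):
    design, table, _ = tiny_partial
    sub = table.iloc[:1200]
    full = fit_free(mimic_spec(design.indicators, design.predictors[:3]),
                    sub, OPT)
    nested = fit_free(mimic_spec(design.indicators, design.predictors[:3],
                                 zero_paths=design.predictors[:1]), sub, OPT)
    d_aic = full.aic - nested.aic
    assert d_aic == pytest.approx(
        -2 * (full.loglik - nested.loglik) + 2 * (full.k_free - nested.k_free),
        abs=1e-8)


def test_lrt_identical_models(tiny_partial, tiny_spec):
    _, table, _ = tiny_partial
    fit = fit_free(tiny_spec, table.iloc[:1000], OPT)
    stat, df, p = likelihood_ratio_test(fit, fit)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert df == 0
    assert p == 1.0


def test_lrt_df_bookkeeping(tiny_partial):
    design, table, _ = tiny_partial
    sub = table.iloc[:1200]
    preds = design.predictors[:4]
    full = fit_free(mimic_spec(design.indicators, preds), sub, OPT)
    nested = fit_free(mimic_spec(design.indicators, preds,
                                 zero_paths=preds[:3]), sub, OPT)
    stat, df, p = likelihood_ratio_test(full, nested)
    assert df == 3
    assert stat >= 0


def test_lrt_rejects_non_nested(tiny_partial):
    design, table, _ = tiny_partial
    sub = table.iloc[:1200]
    f1 = fit_free(mimic_spec(design.indicators, design.predictors[:2]), sub, OPT)
    f2 = fit_free(mimic_spec(design.indicators, design.predictors[2:4]), sub, OPT)
    with pytest.raises(ModelError):
        likelihood_ratio_test(f1, f2)


def test_rsquare_formula_arithmetic():
    # r2 = 0.5, n = 101, k = 10 -> adjusted = 1 - 0.5 * 100 / 90
    from mimiclasso.fit import FitResult
    spec = mimic_spec(tuple("abcde"), tuple(f"x{i}" for i in range(10)))
    beta = np.zeros(10)
    beta[0] = 1.0
    params = Parameters(lam=np.ones(5), nu=np.zeros(5), theta=np.ones(5),
                        beta=beta, psi=1.0, mu_x=np.zeros(10),
                        sigma_x=np.eye(10))
    fit = FitResult(spec=spec, estimates=params, loglik=0.0, loglik_cond=0.0,
                    n_used=101, k_free=0, converged=True)
    r2, r2a = rsquare_latent(fit)
    assert r2 == pytest.approx(0.5)
    assert r2a == pytest.approx(1 - 0.5 * 100 / 90)


def test_rsquare_recovers_population(tiny_partial, tiny_spec):
    design, table, _ = tiny_partial
    fit = fit_free(tiny_spec, table, OPT)
    r2, r2a = rsquare_latent(fit)
    assert r2 == pytest.approx(ch.population_r2(design, "combined"), abs=0.03)
    assert r2a <= r2


def test_observed_and_sandwich_se_agree_on_gaussian_data():
    """On correctly specified Gaussian data the two SE estimators agree
    within 10%."""
    d = ch.make_design("partial", 10_000, 0.5, seed=34, preset="tiny",
                       n_signal_per_tissue=1)
    table, _ = ch.generate_cohort(d)
    name = [n for n, v in d.true_beta.items() if v > 0][0]
    spec = mimic_spec(d.indicators, (name,))
    fit = fit_free(spec, table, FitOptions(se=True, robust=True))
    for key, se in fit.se.items():
        if se > 1e-10:
            assert fit.se_robust[key] == pytest.approx(se, rel=0.10)


def test_loglik_fiml_requires_observed_rows(tiny_spec, tiny_partial):
    design, table, _ = tiny_partial
    params = ch.design_parameters(design)
    sub = table.iloc[:50].copy()
    cols = list(tiny_spec.modeled)
    sub.loc[sub.index[0], cols] = np.nan
    with pytest.raises(ValueError, match="row"):
        loglik_fiml(tiny_spec, params, sub)
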