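"""Penalized estimation: limits, oracle equivalence, path behaviour."""

import numpy as np
import pytest

from mimiclasso import cohort as ch
from mimiclasso import penalty as pn
from mimiclasso.fit import FitOptions, fit_free
from mimiclasso.model import ModelError, mimic_spec


@pytest.fixture(scope="module")
def reg_spec(regression_data):
    df, _ = regression_data
    return mimic_spec(("y",), tuple(f"x{i}" for i in range(20)))


def test_negative_weight_rejected(tiny_partial, tiny_spec):
    _, table, _ = tiny_partial
    with pytest.raises(ModelError):
        pn.fit_penalized(tiny_spec, table, -1.0)


def test_zero_weight_matches_free_fit(tiny_partial, tiny_spec):
    _, table, _ = tiny_partial
    pf = pn.fit_penalized(tiny_spec, table, 0.0)
    fr = fit_free(tiny_spec, table, FitOptions(se=False))
    for i, name in enumerate(tiny_spec.predictors):
        assert pf.beta_raw[name] == pytest.approx(
            fr.estimates.beta[i], abs=1e-4)


def test_saturating_weight_zeroes_all_paths(tiny_partial, tiny_spec):
    _, table, _ = tiny_partial
    pf = pn.fit_penalized(tiny_spec, table, 1e6)
    assert pf.n_nonzero == 0
    assert all(v == 0.0 for v in pf.beta_std.values())


def test_covariate_paths_never_thresholded(tiny_partial):
    design, table, _ = tiny_partial
    spec = mimic_spec(design.indicators, design.predictors + ("tiv",),
                      covariates=("tiv",))
    pf = pn.fit_penalized(spec, table, 1e6)
    assert all(pf.beta_std[n] == 0.0 for n in spec.penalized)
    # the covariate path is estimated freely even at a saturating weight
    assert abs(pf.beta_std["tiv"]) > 0.01


def test_degenerate_spec_matches_lasso_oracle(regression_data, reg_spec):
    """Single-indicator spec == observed-outcome lasso: compare the whole
    path against coordinate descent at the KKT-equivalent alpha."""
    from sklearn.linear_model import Lasso
    df, _ = regression_data
    path = pn.fit_path(reg_spec, df)
    X = df[[f"x{i}" for i in range(20)]].to_numpy()
    Xs = (X - X.mean(0)) / X.std(0)
    y = df["y"].to_numpy()
    assert len(path) == 40
    for f in path:
        alpha = f.penalty_weight * f.estimates.psi / 2.0
        oracle = Lasso(alpha=alpha, fit_intercept=True, tol=1e-10,
                       max_iter=200_000).fit(Xs, y)
        np.testing.assert_allclose(f.estimates.beta, oracle.coef_, atol=1e-3)


def test_degenerate_path_nonzero_monotone(regression_data, reg_spec):
    df, _ = regression_data
    path = pn.fit_path(reg_spec, df)
    nnz = [f.n_nonzero for f in path]
    assert nnz[0] == 0
    assert all(a <= b for a, b in zip(nnz, nnz[1:]))


def test_kkt_conditions_along_path(regression_data, reg_spec):
    """Every grid solution satisfies the lasso stationarity conditions of
    the smooth objective within 1e-4."""
    df, _ = regression_data
    opts = pn.PenaltyOptions()
    problem = pn._Problem(reg_spec, df, opts)
    path = pn.fit_path(reg_spec, df, options=opts)
    for f in path[::4]:
        x = f.free_vector
        _, g = problem.smooth(x)
        for pos in problem.pen_pos:
            b = x[pos]
            if abs(b) > 1e-10:
                assert abs(g[pos] + np.sign(b) * f.penalty_weight) < 1e-4
            else:
                assert abs(g[pos]) <= f.penalty_weight + 1e-4


def test_objective_monotone_within_solve(regression_data, reg_spec):
    df, _ = regression_data
    opts = pn.PenaltyOptions()
    problem = pn._Problem(reg_spec, df, opts)
    hist = []
    pn._prox_solve(problem, 0.05, problem.init_vector(), opts, history=hist)
    assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))


def test_weight_max_definition(tiny_partial, tiny_spec):
    _, table, _ = tiny_partial
    wmax = pn.weight_max(tiny_spec, table)
    at_max = pn.fit_penalized(tiny_spec, table, wmax)
    assert at_max.n_nonzero == 0
    below = pn.fit_penalized(tiny_spec, table, wmax * 0.8)
    assert below.n_nonzero > 0


def test_grid_validation():
    with pytest.raises(ModelError):
        pn.PenaltyGrid(np.array([1.0, 1.0]))
    with pytest.raises(ModelError):
        pn.PenaltyGrid(np.array([0.5, 1.0]))
    g = pn.PenaltyGrid.log_spaced(2.0, 10)
    assert g.weights.size == 10
    assert g.weights[0] == pytest.approx(2.0)


def test_single_weight_grid_equals_fit_penalized(tiny_partial, tiny_spec):
    _, table, _ = tiny_partial
    w = 0.1
    path = pn.fit_path(tiny_spec, table, pn.PenaltyGrid(np.array([w])))
    single = pn.fit_penalized(tiny_spec, table, w)
    assert len(path) == 1
    # both start points converge to the same optimum up to solver tolerance
    for name in tiny_spec.predictors:
        assert path[0].beta_std[name] == pytest.approx(
            single.beta_std[name], abs=5e-4)


def test_selection_consistency(tiny_partial):
    """BIC selection retains the true predictors with strong signal."""
    design, table, _ = tiny_partial
    true = {n for n, v in design.true_beta.items() if v > 0}
    hits = 0
    n_rep = 20
    for s in range(n_rep):
        d = ch.make_design("partial", 2000, 0.5, seed=500 + s, preset="tiny")
        t, _ = ch.generate_cohort(d)
        spec = mimic_spec(d.indicators, d.predictors)
        path = pn.fit_path(spec, t)
        sel = pn.select_penalty(path)
        sv = pn.survivors(sel)
        if true <= set(sv.names):
            hits += 1
    assert hits >= int(0.9 * n_rep)


def test_select_penalty_tie_breaks_sparser(tiny_partial, tiny_spec):
    _, table, _ = tiny_partial
    path = pn.fit_path(tiny_spec, table,
                       pn.PenaltyGrid(np.array([0.3, 0.2])))
    a, b = path
    # force an exact tie, then the larger weight must win
    b.n_nonzero = a.n_nonzero
    object.__setattr__(b, "loglik", a.loglik)
    object.__setattr__(b, "loglik_cond", a.loglik_cond)
    chosen = pn.select_penalty([a, b])
    assert chosen.penalty_weight == pytest.approx(0.3)


def test_survivors_trivial_cases(tiny_partial, tiny_spec):
    _, table, _ = tiny_partial
    empty = pn.survivors(pn.fit_penalized(tiny_spec, table, 1e6))
    assert empty.names == ()
    one = pn.fit_penalized(tiny_spec, table, 1e6)
    name = tiny_spec.predictors[3]
    one.beta_std[name] = 0.2
    assert pn.survivors(one).names == (name,)


def test_scale_invariance_of_standardized_solution(tiny_partial, tiny_spec):
    """Doubling predictor scales leaves the standardized solution alone
    (internal standardization contract)."""
    _, table, _ = tiny_partial
    f1 = pn.fit_penalized(tiny_spec, table, 0.05)
    doubled = table.copy()
    for c in tiny_spec.predictors:
        doubled[c] = doubled[c] * 2.0
    f2 = pn.fit_penalized(tiny_spec, doubled, 0.05)
    for name in tiny_spec.predictors:
        assert f1.beta_std[name] == pytest.approx(f2.beta_std[name], abs=1e-6)


def test_path_bit_reproducible(tiny_partial, tiny_spec):
    _, table, _ = tiny_partial
    grid = pn.PenaltyGrid.log_spaced(0.5, 8)
    p1 = pn.fit_path(tiny_spec, table, grid)
    p2 = pn.fit_path(tiny_spec, table, grid)
    for a, b in zip(p1, p2):
        assert a.objective_value == b.objective_value
        np.testing.assert_array_equal(a.free_vector, b.free_vector)


def test_fiml_penalized_mode_runs(tiny_partial):
    design, table, _ = tiny_partial
    t = table.iloc[:600].copy()
    t.loc[t.index[:100], design.indicators[0]] = np.nan
    spec = mimic_spec(design.indicators, design.predictors[:4])
    opts = pn.PenaltyOptions(missing="fiml", tol=1e-7)
    f = pn.fit_penalized(spec, t, 0.1, opts)
    assert f.converged
    assert f.n_used == 600      # partial rows retained under FIML
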