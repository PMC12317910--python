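import numpy as np
import pytest

from aftfuse.penalties import PenaltySpec, penalty_value
from aftfuse.solver import (
    _GramProblem,
    lambda_grid,
    select_bic,
    select_cv,
    solve,
    stute_weight_vector,
)


def _wls(y, X, w):
    sq = np.sqrt(w)
    return np.linalg.lstsq(X * sq[:, None], y * sq, rcond=None)[0]


def test_vanishing_penalty_recovers_weighted_ols():
    rng = np.random.default_rng(0)
    n, d = 120, 4
    X = rng.standard_normal((n, d))
    beta = np.array([1.0, -2.0, 0.5, 0.0])
    y = X @ beta + 0.1 * rng.standard_normal(n)
    w = np.full(n, 1.0 / n)
    spec = PenaltySpec(lambda1=1e-10, lambda2=1e-10)
    got = solve(y, X, w, spec, pen_block=[1, 1, 2, 2])
    np.testing.assert_allclose(got, _wls(y, X, w), atol=1e-6)


def test_orthonormal_design_reduces_to_scalar_thresholding():
    from aftfuse.penalties import threshold_update

    rng = np.random.default_rng(1)
    n, d = 400, 5
    X, _ = np.linalg.qr(rng.standard_normal((n, d)))
    X *= np.sqrt(n)  # columns with unit empirical second moment
    beta = np.array([2.0, -0.05, 0.8, 0.0, -1.5])
    y = X @ beta
    w = np.full(n, 1.0 / n)
    lam = 0.6
    spec = PenaltySpec(lambda1=lam, lambda2=lam)
    got = solve(y, X, w, spec, pen_block=[1] * d)
    ols = _wls(y, X, w)
    expected = [threshold_update(2 * b, 2.0, lam, "mcp", 3.0) for b in ols]
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_exact_zeros_in_solution():
    rng = np.random.default_rng(2)
    n = 200
    X = rng.standard_normal((n, 3))
    y = X[:, 0] * 2.0 + 0.05 * rng.standard_normal(n)
    w = np.full(n, 1.0 / n)
    got = solve(y, X, w, PenaltySpec(lambda1=0.4, lambda2=0.4), pen_block=[1, 1, 1])
    assert got[1] == 0.0 and got[2] == 0.0 and got[0] != 0.0


def test_matches_brute_force_grid_on_tiny_instances():
    """Coordinate descent attains the global penalized optimum (2-D exhaustive search)."""
    rng = np.random.default_rng(4)
    grid = np.arange(-3.0, 3.0, 0.01)
    B1, B2 = np.meshgrid(grid, grid, indexing="ij")
    for trial in range(200):
        n = int(rng.integers(8, 31))
        X = rng.standard_normal((n, 2)) @ np.array([[1.0, 0.4], [0.0, 1.0]])
        beta = rng.choice([-2.0, -1.0, 0.0, 1.0, 2.0], size=2)
        y = X @ beta + 0.3 * rng.standard_normal(n)
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        w = stute_weight_vector(rng.exponential(1.0, n) + 0.01, event)
        lam = float(rng.uniform(0.05, 0.8))
        spec = PenaltySpec(lambda1=lam, lambda2=lam)
        got = solve(y, X, w, spec, pen_block=[1, 1])
        # evaluate the standardized objective on the same scale as the solver
        prob = _GramProblem(y, X, w, np.array([1, 1]))
        obj = lambda b1, b2: (
            prob.yy
            - 2 * (prob.c[0] * b1 + prob.c[1] * b2)
            + prob.G[0, 0] * b1**2 + 2 * prob.G[0, 1] * b1 * b2 + prob.G[1, 1] * b2**2
            + penalty_value(np.abs(b1), lam, "mcp", 3.0)
            + penalty_value(np.abs(b2), lam, "mcp", 3.0)
        )
        vals = obj(B1, B2)
        k = np.unravel_index(np.argmin(vals), vals.shape)
        got_std = got * prob.scales
        assert obj(got_std[0], got_std[1]) <= vals[k] + 1e-8


def test_objective_monotone_across_sweeps():
    rng = np.random.default_rng(6)
    n, d = 150, 8
    X = rng.standard_normal((n, d))
    y = X[:, 0] - X[:, 3] + 0.2 * rng.standard_normal(n)
    w = np.full(n, 1.0 / n)
    pb = np.array([1] * d)
    prob = _GramProblem(y, X, w, pb)
    spec = PenaltySpec(lambda1=0.2, lambda2=0.2)

    def pen_obj(theta):
        return prob.loss(theta) + float(
            np.sum(penalty_value(np.abs(theta[pb > 0]), 0.2, "mcp", 3.0))
        )

    theta = np.zeros(d)
    prev = pen_obj(theta)
    for _ in range(30):
        theta, _ = prob.solve_at(0.2, 0.2, spec, warm=theta, max_iter=1)
        cur = pen_obj(theta)
        assert cur <= prev + 1e-10
        prev = cur


def test_lambda_grid_properties():
    rng = np.random.default_rng(7)
    n = 100
    X = rng.standard_normal((n, 4))
    y = X[:, 0] + rng.standard_normal(n) * 0.1
    w = np.full(n, 1.0 / n)
    pb = [1, 1, 2, 2]
    pairs = lambda_grid(y, X, w, pb, n1=15, n2=15)
    assert pairs.shape == (225, 2)
    pairs2 = lambda_grid(2 * y, X, w, pb, n1=15, n2=15)
    np.testing.assert_allclose(pairs2, 2 * pairs, rtol=1e-10)  # gradient linearity
    with pytest.raises(ValueError, match="degenerate"):
        lambda_grid(np.zeros(n), X, w, pb)


def test_select_cv_deterministic_and_support_recovery():
    rng = np.random.default_rng(8)
    n, p = 500, 10
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:3] = [3.0, -3.0, 2.0]
    y = X @ beta + 0.05 * rng.standard_normal(n)
    time = np.exp(y - y.min() + 0.1)
    event = np.ones(n, int)
    pb = [1] * p
    out1 = select_cv(y, X, time, event, pb, PenaltySpec(), K=5, seed=3)
    out2 = select_cv(y, X, time, event, pb, PenaltySpec(), K=5, seed=3)
    assert out1[0] == out2[0] and out1[3] == out2[3]
    coefs = out1[2].coefs[out1[3]]
    assert set(np.flatnonzero(coefs != 0)) == {0, 1, 2}


def test_select_bic_agrees_with_cv_on_strong_signal():
    rng = np.random.default_rng(12)
    n, p = 400, 8
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:2] = [2.5, -2.5]
    y = X @ beta + 0.1 * rng.standard_normal(n)
    time = np.exp(y - y.min() + 0.1)
    event = np.ones(n, int)
    w = stute_weight_vector(time, event)
    pb = [1] * p
    l1c, _, path_c, kc = select_cv(y, X, time, event, pb, PenaltySpec(), K=5, seed=1)
    l1b, _, path_b, kb = select_bic(y, X, w, pb, PenaltySpec())
    supp_cv = set(np.flatnonzero(path_c.coefs[kc] != 0))
    supp_bic = set(np.flatnonzero(path_b.coefs[kb] != 0))
    assert supp_cv == supp_bic == {0, 1}


def test_bic_df_nonincreasing_in_lambda1():
    rng = np.random.default_rng(13)
    n, p = 300, 6
    X = rng.standard_normal((n, p))
    y = X[:, 0] * 2 - X[:, 1] + 0.3 * rng.standard_normal(n)
    w = np.full(n, 1.0 / n)
    _, _, path, _ = select_bic(y, X, w, [1] * p, PenaltySpec(), n1=15, n2=1)
    lam1 = path.lambdas[:, 0]
    order = np.argsort(-lam1)
    df = path.df[order]
    assert np.all(np.diff(df) >= -1)  # near-monotone up to CD tolerance


def test_cv_rejects_too_few_folds_and_zero_mass():
    rng = np.random.default_rng(14)
    n = 40
    X = rng.standard_normal((n, 2))
    y = X[:, 0] + 0.1 * rng.standard_normal(n)
    time = np.exp(y - y.min() + 0.1)
    with pytest.raises(ValueError):
        select_cv(y, X, time, np.ones(n, int), [1, 1], K=1)
    with pytest.raises(ValueError, match="zero (Stute|total) mass"):
        select_cv(y, X, time, np.zeros(n, int), [1, 1], K=5, seed=0)
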