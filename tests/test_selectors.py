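"""The four single filters: contracts, hand arithmetic and brute-force oracles."""

import math

import numpy as np
import pytest

from wgdipc import (
    LassoNonConvergenceError,
    LassoSelector,
    lasso_select,
    mic_scores,
    mic_select,
    relief_select,
    relief_weights,
    ridge_select,
)
from wgdipc.selectors import relief_diff

SELECT_FUNCS = {
    "lasso": lasso_select,
    "ridge": ridge_select,
    "mic": mic_select,
    "relief": relief_select,
}


@pytest.mark.parametrize("method", sorted(SELECT_FUNCS))
class TestSelectorContract:
    def test_returns_exactly_n_distinct_inrange_sorted(self, method, random_problem):
        X, y = random_problem
        res = SELECT_FUNCS[method](X, y, 7)
        assert len(res.selected) == 7 == len(set(res.selected))
        assert res.selected == sorted(res.selected)
        assert all(0 <= i < X.shape[1] for i in res.selected)
        assert res.scores.shape == (X.shape[1],)

    def test_deterministic_given_identical_inputs(self, method, random_problem):
        X, y = random_problem
        a = SELECT_FUNCS[method](X, y, 5)
        b = SELECT_FUNCS[method](X, y, 5)
        assert a.selected == b.selected
        assert np.array_equal(a.scores, b.scores)

    def test_n_equals_all_features_returns_all(self, method, random_problem):
        X, y = random_problem
        res = SELECT_FUNCS[method](X, y, X.shape[1])
        assert res.selected == list(range(X.shape[1]))

    def test_planted_features_recovered(self, method, small_planted):
        matrix, planted = small_planted
        res = SELECT_FUNCS[method](matrix.X, matrix.y, 20)
        assert set(planted) <= set(res.selected)


class TestLasso:
    def test_convergence_count_lies_in_band(self, small_planted):
        matrix, _ = small_planted
        res = lasso_select(matrix.X, matrix.y, 20)
        d = res.diagnostics
        assert d["converged"]
        assert 20 <= d["count_at_convergence"] <= 20 * 1.05 + 1e-9

    def test_selected_count_nondecreasing_in_budget(self, small_planted):
        # the dichotomy relies on a positive budget/selection-count relation
        matrix, _ = small_planted
        trace = lasso_select(matrix.X, matrix.y, 20).diagnostics["trace"]
        by_c = sorted(trace)
        counts = [cnt for _c, cnt in by_c]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_planted_regression_recovers_determinants(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 40))
        beta = np.zeros(40)
        beta[[2, 11, 17, 23, 31]] = [3.0, -2.5, 2.0, 4.0, -3.5]
        y = X @ beta + 0.01 * rng.normal(size=80)
        res = lasso_select(X, y, 5)
        assert set(res.selected) == {2, 11, 17, 23, 31}

    def test_non_convergence_raises_and_fallback_recovers(self, random_problem):
        X, y = random_problem
        tight = dict(max_bisect_iter=1, max_restarts=0)
        with pytest.raises(LassoNonConvergenceError):
            lasso_select(X, y, 5, **tight)
        res = lasso_select(X, y, 5, fallback="last_c", **tight)
        assert len(res.selected) == 5 and res.diagnostics["converged"] is False

    def test_invalid_config_rejected(self, random_problem):
        X, y = random_problem
        with pytest.raises(ValueError):
            lasso_select(X, y, 0)
        with pytest.raises(ValueError):
            lasso_select(X, y, 5, band_factor=1.0)
        with pytest.raises(ValueError):
            lasso_select(X, y, 5, initial_interval=(-1.0, 10.0))


class TestRidge:
    def test_column_equal_to_response_wins_and_matches_closed_form(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        y = Xs[:, 2].copy()
        res = ridge_select(X, y, 1)
        assert res.selected == [2]
        # closed form b = (X'X + lambda I)^-1 X'y on the standardized data
        lam = res.diagnostics["lambda"]
        b = np.linalg.solve(Xs.T @ Xs + lam * np.eye(4), Xs.T @ (y - y.mean()))
        assert np.allclose(res.scores, np.abs(b), atol=1e-8)

    def test_constant_column_ranked_last(self, random_problem):
        X, y = random_problem
        X = X.copy()
        X[:, 4] = 2.5
        res = ridge_select(X, y, X.shape[1])
        assert res.scores[4] == pytest.approx(0.0, abs=1e-12)
        assert res.scores[4] <= res.scores.min() + 1e-12

    def test_lambda_comes_from_grid(self, random_problem):
        X, y = random_problem
        grid = [0.1, 1.0, 10.0]
        res = ridge_select(X, y, 3, lambda_grid=grid)
        assert res.diagnostics["lambda"] in grid
        with pytest.raises(ValueError):
            ridge_select(X, y, 3, lambda_grid=[0.0, 1.0])


def mic_oracle(x, y, m):
    """Brute-force MIC: enumerate equal-frequency grids with pure-python dicts."""
    cap = math.floor(m**0.6)

    def bins(values, nbins):
        order = sorted(range(m), key=lambda i: values[i])
        assign = [0] * m
        for rank, i in enumerate(order):
            assign[i] = (rank * nbins) // m
        return assign, len(set(assign))

    best = 0.0
    for nx in range(2, cap + 1):
        for ny in range(2, cap + 1):
            if nx * ny > cap:
                continue
            xb, nxa = bins(x, nx)
            yb, nya = bins(y, ny)
            if nxa < 2 or nya < 2:
                continue
            joint, margx, margy = {}, {}, {}
            for i in range(m):
                joint[(xb[i], yb[i])] = joint.get((xb[i], yb[i]), 0) + 1
                margx[xb[i]] = margx.get(xb[i], 0) + 1
                margy[yb[i]] = margy.get(yb[i], 0) + 1
            mi = 0.0
            for (bx, by), c in joint.items():
                p = c / m
                mi += p * math.log(p * m * m / (margx[bx] * margy[by]))
            best = max(best, mi / math.log(min(nxa, nya)))
    return best


class TestMic:
    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        m = 40
        X = rng.normal(size=(m, 6))
        X[:, 0] = np.linspace(0, 1, m) + 0.01 * rng.normal(size=m)
        y = X[:, 0] + 0.5 * rng.normal(size=m)
        got = mic_scores(X, y)
        for j in range(X.shape[1]):
            assert got[j] == pytest.approx(
                mic_oracle(list(X[:, j]), list(y), m), abs=1e-12
            )

    def test_step_function_of_feature_scores_high(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=200)
        y = (x > np.median(x)).astype(int)
        X = np.column_stack([x, rng.normal(size=200)])
        scores = mic_scores(X, y)
        assert scores[0] >= 0.9

    def test_dependent_feature_outranks_independent_noise(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(size=200)
            y = (x > 0.5).astype(int)
            X = np.column_stack([x, rng.uniform(size=200)])
            scores = mic_scores(X, y)
            wins += scores[1] < scores[0]
        assert wins >= 95

    def test_duplicated_columns_score_identically(self, random_problem):
        X, y = random_problem
        X2 = np.column_stack([X[:, 0], X[:, 0], X[:, 1]])
        scores = mic_scores(X2, y)
        assert scores[0] == scores[1]

    def test_column_permutation_equivariance(self, small_planted):
        matrix, _ = small_planted
        X = matrix.X[:, :40]
        perm = np.random.default_rng(0).permutation(40)
        base = mic_select(X, matrix.y, 5).selected
        permuted = mic_select(X[:, perm], matrix.y, 5).selected
        assert sorted(np.argsort(perm)[base]) == permuted  # noqa: C414

    def test_constant_feature_scores_zero(self, random_problem):
        X, y = random_problem
        X = X.copy()
        X[:, 0] = 1.0
        assert mic_scores(X, y)[0] == 0.0

    def test_too_few_samples_rejected(self):
        X = np.zeros((6, 3))
        with pytest.raises(ValueError, match="grid cap"):
            mic_scores(X, np.array([0, 1, 0, 1, 0, 1]))

    def test_dp_estimator_refines_never_below_equipartition(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 4))
        y = (X[:, 1] > 0).astype(int)
        eq = mic_scores(X, y, estimator="equipartition")
        dp = mic_scores(X, y, estimator="mine")
        assert np.all(dp >= eq - 1e-12)


def relief_oracle(X, y, k=1):
    """Independent Relief pass: every sample once, plain python loops."""
    m, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = [s if s else 1.0 for s in sd]
    Z = [[(X[i][a] - mu[a]) / sd[a] for a in range(p)] for i in range(m)]
    span = [X[:, a].max() - X[:, a].min() for a in range(p)]
    W = [0.0] * p

    def dist(i, j):
        return math.sqrt(sum((Z[i][a] - Z[j][a]) ** 2 for a in range(p)))

    for r in range(m):
        hits = sorted(
            (i for i in range(m) if i != r and y[i] == y[r]), key=lambda i: dist(r, i)
        )[:k]
        misses = sorted(
            (i for i in range(m) if y[i] != y[r]), key=lambda i: dist(r, i)
        )[:k]
        for a in range(p):
            if span[a] == 0:
                continue
            dh = sum(abs(X[r][a] - X[h][a]) for h in hits) / (k * span[a])
            dm = sum(abs(X[r][a] - X[mi][a]) for mi in misses) / (k * span[a])
            W[a] += (dm - dh) / m
    return np.array(W)


class TestRelief:
    def test_diff_arithmetic(self):
        assert relief_diff(0.5, 0.25, 0.0, 1.0) == pytest.approx(0.25)
        # a 0/1 feature reproduces the discrete branch exactly
        assert relief_diff(1.0, 1.0, 0.0, 1.0) == 0.0
        assert relief_diff(1.0, 0.0, 0.0, 1.0) == 1.0
        # constant feature: difference defined as 0
        assert relief_diff(3.0, 3.0, 3.0, 3.0) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 6))
        y = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        X[:, 2] += 2.0 * y
        got = relief_weights(X, y, k_neighbors=1)
        assert np.allclose(got, relief_oracle(X, y, k=1), atol=1e-10)

    def test_separating_feature_has_strictly_largest_weight(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 8))
        y = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        X[:, 5] = y + 0.01 * rng.normal(size=40)
        W = relief_weights(X, y, k_neighbors=1)
        assert np.argmax(W) == 5
        assert W[5] > np.max(np.delete(W, 5))

    def test_weights_bounded_by_one(self, small_planted):
        matrix, _ = small_planted
        W = relief_weights(matrix.X, matrix.y)
        assert np.all(np.abs(W) <= 1.0)

    def test_small_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="k_neighbors"):
            relief_weights(X, y, k_neighbors=2)

    def test_theta_mode(self, random_problem):
        X, y = random_problem
        W = relief_weights(X, y)
        empty = relief_select(X, y, 5, theta=float(W.max()) + 1.0)
        assert empty.selected == []
        some = relief_select(X, y, 5, theta=float(np.median(W)))
        assert set(some.selected) == set(np.flatnonzero(W >= np.median(W)))

    def test_subsampled_pass_is_seeded(self, random_problem):
        X, y = random_problem
        a = relief_weights(X, y, m_samples=30, random_state=7)
        b = relief_weights(X, y, m_samples=30, random_state=7)
        assert np.array_equal(a, b)


class TestLassoSelectorEstimator:
    def test_transform_selects_columns(self, small_planted):
        matrix, planted = small_planted
        sel = LassoSelector(n_features_to_select=10).fit(matrix.X, matrix.y)
        assert sel.transform(matrix.X).shape == (matrix.n_samples, 10)
        assert set(planted) <= set(sel.selected_)
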