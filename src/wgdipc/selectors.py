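"""The four single filters: Lasso, Ridge, MIC and Relief.

Each filter scores the 400 composition features against the class labels and
returns exactly ``n`` selected feature indices (sorted), with per-feature
scores and method-specific diagnostics. All four are exposed both as
scikit-learn selector estimators (``fit`` / ``transform`` /
``get_support``) and as thin functional wrappers returning a
:class:`SelectorResult`.

Conventions shared by all filters:

* features are standardized (zero mean, unit variance) before penalized
  fits so coefficient magnitudes are comparable;
* binary labels become a 0/1 regression target; multiclass labels become
  one-vs-rest indicator targets with per-feature score = max |coefficient|
  across classes (integer-coded multiclass regression would impose an
  arbitrary class ordering); a genuinely continuous response is used as-is;
* ties are always broken by ascending feature index, so results are
  reproducible bit-for-bit given identical inputs and configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_X_y, check_is_fitted

__all__ = [
    "SelectorResult",
    "LassoNonConvergenceError",
    "LassoSelector",
    "RidgeSelector",
    "MICSelector",
    "ReliefSelector",
    "lasso_select",
    "ridge_select",
    "mic_select",
    "relief_select",
    "mic_scores",
    "relief_weights",
    "relief_diff",
]


@dataclass
class SelectorResult:
    """One filter's output: scores, the selected index set and diagnostics."""

    method: str
    selected: list[int]
    scores: np.ndarray
    diagnostics: dict[str, Any] = field(default_factory=dict)


class LassoNonConvergenceError(RuntimeError):
    """The dichotomy on the Lasso budget failed to land in the target band."""


# ---------------------------------------------------------------------------
# shared helpers


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


def _response_matrix(y: np.ndarray) -> np.ndarray:
    """Regression target(s) for the penalized filters.

    Binary class codes -> one 0/1 column; >=3 classes -> one-vs-rest
    indicators; continuous y -> itself as a single column.
    """
    y = np.asarray(y)
    if y.dtype.kind == "f" and not np.all(y == np.round(y)):
        return y.reshape(-1, 1).astype(float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("response must have at least 2 distinct values")
    if classes.size == 2:
        return (y == classes[1]).astype(float).reshape(-1, 1)
    return np.column_stack([(y == c).astype(float) for c in classes])


def _top_n(scores: np.ndarray, n: int) -> list[int]:
    """Indices of the n largest scores, ties broken by ascending index."""
    order = np.lexsort((np.arange(scores.size), -scores))
    return sorted(int(i) for i in order[:n])


def _resolve_n(n: int, n_features: int) -> int:
    if not 1 <= n <= n_features:
        raise ValueError(
            f"n_features_to_select must lie in [1, {n_features}], got {n}"
        )
    return int(n)


class _BaseFilterSelector(SelectorMixin, BaseEstimator):
    """Shared fitted-attribute plumbing for the four filters."""

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def _finalize(self, n_features: int, selected: list[int], scores: np.ndarray,
                  diagnostics: dict[str, Any]) -> None:
        mask = np.zeros(n_features, dtype=bool)
        mask[selected] = True
        self.support_ = mask
        self.selected_ = sorted(selected)
        self.scores_ = scores
        self.diagnostics_ = diagnostics

    def result(self) -> SelectorResult:
        check_is_fitted(self, "support_")
        return SelectorResult(
            method=self._method_name,
            selected=list(self.selected_),
            scores=self.scores_,
            diagnostics=dict(self.diagnostics_),
        )


# ---------------------------------------------------------------------------
# Lasso


class LassoSelector(_BaseFilterSelector):
    """L1 selection driven by a dichotomy on the budget constant c.

    The budget maps monotonically to the penalty weight (``alpha = 1 / c``):
    larger c means a weaker penalty and more nonzero coefficients, so the
    number of selected variables is nondecreasing in c. Bisection over
    ``initial_interval`` stops when the nonzero count lies in
    ``[n, band_factor * n]``; after ``max_bisect_iter`` failed iterations the
    interval is magnified by ``restart_scale`` and the search restarts, up to
    ``max_restarts`` times. At convergence the n variables with largest
    |coefficient| are returned.

    Parameters
    ----------
    n_features_to_select : int
        Target n. The pre-truncation count at convergence lies in
        [n, band_factor * n].
    fallback : {"error", "last_c"}
        What to do if the dichotomy never converges: raise
        :class:`LassoNonConvergenceError` (default, the documented behaviour)
        or take the top-n |coefficient| at the last evaluated c.
    """

    _method_name = "lasso"

    def __init__(
        self,
        n_features_to_select: int = 100,
        initial_interval: tuple[float, float] = (0.0, 1e6),
        band_factor: float = 1.05,
        max_bisect_iter: int = 100,
        max_restarts: int = 10,
        restart_scale: float = 10.0,
        fallback: str = "error",
        lasso_max_iter: int = 3000,
        lasso_tol: float = 1e-4,
    ) -> None:
        self.n_features_to_select = n_features_to_select
        self.initial_interval = initial_interval
        self.band_factor = band_factor
        self.max_bisect_iter = max_bisect_iter
        self.max_restarts = max_restarts
        self.restart_scale = restart_scale
        self.fallback = fallback
        self.lasso_max_iter = lasso_max_iter
        self.lasso_tol = lasso_tol

    def _coef_scores(self, Xs: np.ndarray, Y: np.ndarray, c: float) -> np.ndarray:
        """Per-feature max |coefficient| at budget c; c <= 0 selects nothing."""
        if c <= 0.0:
            return np.zeros(Xs.shape[1])
        alpha = 1.0 / c
        coefs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for j in range(Y.shape[1]):
                model = Lasso(
                    alpha=alpha, max_iter=self.lasso_max_iter, tol=self.lasso_tol
                )
                model.fit(Xs, Y[:, j])
                coefs.append(np.abs(model.coef_))
        return np.max(coefs, axis=0)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LassoSelector":
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        p = X.shape[1]
        n = _resolve_n(self.n_features_to_select, p)
        if self.band_factor <= 1.0:
            raise ValueError("band_factor must exceed 1")
        if self.initial_interval[0] < 0:
            raise ValueError("interval lower bound must be >= 0")
        if n == p:
            self._finalize(
                p, list(range(p)), np.ones(p),
                {"converged": True, "c": None, "iterations": 0, "restarts": 0,
                 "count_at_convergence": p, "trace": []},
            )
            return self
        Xs = _standardize(X)
        Y = _response_matrix(y)
        band_hi = self.band_factor * n + 1e-9
        trace: list[tuple[float, int]] = []
        total_iters = 0
        last_scores = np.zeros(p)
        last_c = None
        for restart in range(self.max_restarts + 1):
            scale = self.restart_scale**restart
            lo, hi = self.initial_interval[0] * scale, self.initial_interval[1] * scale
            for _ in range(self.max_bisect_iter):
                mid = 0.5 * (lo + hi)
                scores = self._coef_scores(Xs, Y, mid)
                count = int(np.count_nonzero(scores))
                trace.append((mid, count))
                total_iters += 1
                last_scores, last_c = scores, mid
                if n <= count <= band_hi:
                    selected = _top_n(scores, n)
                    self._finalize(
                        p, selected, scores,
                        {"converged": True, "c": mid, "iterations": total_iters,
                         "restarts": restart, "count_at_convergence": count,
                         "trace": trace},
                    )
                    return self
                if count < n:
                    lo = mid
                else:
                    hi = mid
        diagnostics = {
            "converged": False, "c": last_c, "iterations": total_iters,
            "restarts": self.max_restarts, "count_at_convergence": None,
            "trace": trace,
        }
        if self.fallback == "last_c":
            self._finalize(p, _top_n(last_scores, n), last_scores, diagnostics)
            return self
        raise LassoNonConvergenceError(
            f"lasso dichotomy did not reach a nonzero count in [{n}, {band_hi:.2f}] "
            f"after {self.max_restarts} interval magnifications"
        )


# ---------------------------------------------------------------------------
# Ridge


class RidgeSelector(_BaseFilterSelector):
    """Ridge-coefficient magnitude ranking with a cross-validated lambda grid.

    The penalty lambda is chosen by k-fold grid search minimizing mean
    squared error over a log-spaced grid (default 50 points in
    [1e-4, 1e4]); coefficients b(lambda*) = (X'X + lambda* I)^-1 X'Y are then
    computed on the standardized full data and the n features with largest
    |coefficient| are selected.
    """

    _method_name = "ridge"

    def __init__(
        self,
        n_features_to_select: int = 100,
        lambda_grid: np.ndarray | None = None,
        grid_cv_folds: int = 5,
    ) -> None:
        self.n_features_to_select = n_features_to_select
        self.lambda_grid = lambda_grid
        self.grid_cv_folds = grid_cv_folds

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeSelector":
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        p = X.shape[1]
        n = _resolve_n(self.n_features_to_select, p)
        grid = (
            np.logspace(-4, 4, 50) if self.lambda_grid is None
            else np.asarray(self.lambda_grid, dtype=float)
        )
        if np.any(grid <= 0):
            raise ValueError("all lambda values must be positive")
        Xs = _standardize(X)
        Y = _response_matrix(y)
        n_splits = min(self.grid_cv_folds, Xs.shape[0])
        kf = KFold(n_splits=n_splits)
        splits = list(kf.split(Xs))
        cv_mse = np.zeros(grid.size)
        try:
            for gi, lam in enumerate(grid):
                errs = []
                for tr, te in splits:
                    model = Ridge(alpha=lam).fit(Xs[tr], Y[tr])
                    pred = model.predict(Xs[te]).reshape(len(te), -1)
                    errs.append(np.mean((pred - Y[te]) ** 2))
                cv_mse[gi] = np.mean(errs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"singular ridge fit across the lambda grid {grid[0]}..{grid[-1]}"
            ) from exc
        best = int(np.argmin(cv_mse))
        lam_star = float(grid[best])
        model = Ridge(alpha=lam_star).fit(Xs, Y)
        coef = np.atleast_2d(model.coef_)
        scores = np.max(np.abs(coef), axis=0)
        self._finalize(
            p, _top_n(scores, n), scores,
            {"lambda": lam_star, "cv_mse": cv_mse.tolist(),
             "lambda_grid": grid.tolist()},
        )
        return self


# ---------------------------------------------------------------------------
# MIC


def _equifreq_bins(v: np.ndarray, nbins: int) -> tuple[np.ndarray, int]:
    """Equal-frequency bin assignment; collapses to distinct values when few.

    Returns (bin ids, actual number of occupied bins).
    """
    distinct = np.unique(v)
    if distinct.size <= nbins:
        ids = np.searchsorted(distinct, v)
        return ids, distinct.size
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=np.int64)
    ranks[order] = np.arange(v.size)
    ids = (ranks * nbins) // v.size
    # keep equal values in one bin: assign each distinct value the bin of its
    # first occurrence in sorted order
    sorted_v = v[order]
    sorted_b = ids[order]
    boundaries = np.concatenate(([True], sorted_v[1:] != sorted_v[:-1]))
    canon = sorted_b[boundaries]
    ids = canon[np.searchsorted(sorted_v[boundaries], v)]
    occupied = np.unique(ids)
    ids = np.searchsorted(occupied, ids)
    return ids, occupied.size


def _mutual_information(contingency: np.ndarray) -> float:
    """MI in nats from a joint count table."""
    total = contingency.sum()
    if total == 0:
        return 0.0
    pxy = contingency / total
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px * py))
    return float(np.nansum(terms))


def _mic_single(
    x: np.ndarray, y: np.ndarray, cap: int, estimator: str
) -> float:
    """MIC of one feature against the response.

    Searches all grid shapes (nx columns, ny rows) with nx * ny <= cap and
    nx, ny >= 2, using equal-frequency partitions on both axes
    (``equipartition``) or a dynamic-programming refinement of the x-axis
    partition against an equal-frequency y partition (``mine``); the
    normalized value MI / log(min(nx, ny)) is maximized over shapes.
    """
    if np.unique(x).size < 2:
        return 0.0
    best = 0.0
    max_x = cap // 2
    seen: set[tuple[int, int]] = set()
    for nx in range(2, max_x + 1):
        xb, nxa = _equifreq_bins(x, nx)
        if nxa < 2:
            continue
        max_y = cap // nx
        for ny in range(2, max_y + 1):
            yb, nya = _equifreq_bins(y, ny)
            if nya < 2 or (nxa, nya) in seen:
                continue
            seen.add((nxa, nya))
            table = np.bincount(xb * nya + yb, minlength=nxa * nya).reshape(nxa, nya)
            mi = _mutual_information(table)
            best = max(best, mi / math.log(min(nxa, nya)))
    if estimator == "mine":
        best = max(best, _mic_dp(x, y, cap))
    elif estimator != "equipartition":
        raise ValueError(f"unknown MIC estimator {estimator!r}")
    return min(best, 1.0)


def _mic_dp(x: np.ndarray, y: np.ndarray, cap: int) -> float:
    """DP-optimized x-axis partition against equal-frequency y partitions.

    Candidate x cut points come from a fine equal-frequency super-partition
    (twice the maximal column count); for each y partition the best MI over
    x partitions with t columns is found by dynamic programming.
    """
    best = 0.0
    m = x.size
    max_x = cap // 2
    fine, n_fine = _equifreq_bins(x, min(m, 2 * max_x))
    if n_fine < 2:
        return 0.0
    for ny in range(2, cap // 2 + 1):
        yb, nya = _equifreq_bins(y, ny)
        if nya < 2:
            continue
        max_cols = cap // nya
        if max_cols < 2:
            continue
        # cumulative counts of y bins over ordered fine cells
        counts = np.zeros((n_fine, nya))
        np.add.at(counts, (fine, yb), 1.0)
        cum = np.vstack([np.zeros(nya), np.cumsum(counts, axis=0)])

        def block_entropy_terms(i: int, j: int) -> np.ndarray:
            return cum[j] - cum[i]

        # dp[t][j] = max over partitions of fine cells [0, j) into t columns
        # of sum over cells of sum_y n_xy * log(n_xy / n_x.)
        neg_inf = -np.inf
        n_cells = n_fine
        score = np.full((n_cells + 1, n_cells + 1), neg_inf)
        for i in range(n_cells):
            for j in range(i + 1, n_cells + 1):
                block = block_entropy_terms(i, j)
                tot = block.sum()
                if tot == 0:
                    score[i][j] = 0.0
                    continue
                nz = block[block > 0]
                score[i][j] = float(np.sum(nz * np.log(nz / tot)))
        dp = np.full((max_cols + 1, n_cells + 1), neg_inf)
        dp[0][0] = 0.0
        for t in range(1, max_cols + 1):
            for j in range(t, n_cells + 1):
                cand = dp[t - 1, :j] + score[:j, j]
                dp[t][j] = np.max(cand)
        # convert the partition objective into MI:
        # MI = (1/m) * sum n_xy log(n_xy/n_x.) + H(Y)
        ycounts = np.bincount(yb, minlength=nya).astype(float)
        hy = -np.sum((ycounts / m) * np.log(ycounts / m))
        for t in range(2, max_cols + 1):
            if dp[t][n_cells] == neg_inf:
                continue
            mi = dp[t][n_cells] / m + hy
            if mi > 0:
                best = max(best, mi / math.log(min(t, nya)))
    return best


def mic_scores(
    X: np.ndarray,
    y: np.ndarray,
    grid_exponent: float = 0.6,
    estimator: str = "equipartition",
) -> np.ndarray:
    """MIC of every feature column against the response.

    The grid size cap is B(m) = floor(m ** grid_exponent); sample sizes so
    small that B(m) < 4 (m <= 10 at the default exponent) leave no valid
    2 x 2 grid and are an error. Features with fewer than two distinct
    values score 0. Scores lie in [0, 1].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = y.size
    cap = int(math.floor(m**grid_exponent))
    if cap < 4:
        raise ValueError(
            f"sample count {m} too small: grid cap B(m) = {cap} < 4 leaves no 2x2 grid"
        )
    return np.array(
        [_mic_single(X[:, j], y, cap, estimator) for j in range(X.shape[1])]
    )


class MICSelector(_BaseFilterSelector):
    """Top-n selection by maximal information coefficient."""

    _method_name = "mic"

    def __init__(
        self,
        n_features_to_select: int = 100,
        grid_exponent: float = 0.6,
        estimator: str = "equipartition",
    ) -> None:
        self.n_features_to_select = n_features_to_select
        self.grid_exponent = grid_exponent
        self.estimator = estimator

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MICSelector":
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        n = _resolve_n(self.n_features_to_select, X.shape[1])
        scores = mic_scores(X, y, self.grid_exponent, self.estimator)
        cap = int(math.floor(X.shape[0] ** self.grid_exponent))
        self._finalize(
            X.shape[1], _top_n(scores, n), scores,
            {"grid_cap": cap, "estimator": self.estimator},
        )
        return self


# ---------------------------------------------------------------------------
# Relief


def relief_diff(r_value: float, h_value: float, feat_min: float, feat_max: float) -> float:
    """Per-feature difference |R[A] - H[A]| / (max(A) - min(A)).

    A constant feature (max == min) has difference 0 by convention. A 0/1
    discrete feature reproduces the discrete branch exactly: 0 when the
    values agree and 1 when they differ.
    """
    rng = feat_max - feat_min
    if rng == 0:
        return 0.0
    return abs(r_value - h_value) / rng


def relief_weights(
    X: np.ndarray,
    y: np.ndarray,
    m_samples: int | None = None,
    k_neighbors: int = 5,
    random_state: int | None = None,
) -> np.ndarray:
    """Relief feature weights W(A) from nearest hits and misses.

    For each of m sampled instances R the k nearest same-class neighbours
    (hits H) and, per other class, the k nearest members (misses M) are
    found by Euclidean distance on standardized features. Weights update as

        W(A) <- W(A) - diff(A, R, H) / m + diff(A, R, M) / m

    with diff averaged over the k neighbours and, for more than two classes,
    miss contributions weighted by class prior P(C) / (1 - P(class(R)))
    (ReliefF weighting; for binary data the weight is 1). With the default
    ``m_samples=None`` every instance is visited once in order, making the
    pass deterministic. Each |W(A)| is bounded by 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    m_total, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("Relief needs at least two classes")
    small = counts <= k_neighbors
    if small.any():
        bad = classes[small][0]
        raise ValueError(
            f"class {bad!r} has {int(counts[small][0])} members; "
            f"every class must exceed k_neighbors = {k_neighbors}"
        )
    priors = {c: cnt / m_total for c, cnt in zip(classes, counts)}
    Z = _standardize(X)
    fmin, fmax = X.min(axis=0), X.max(axis=0)
    rng_span = fmax - fmin
    denom = np.where(rng_span == 0.0, np.inf, rng_span)
    D = cdist(Z, Z)
    members = {c: np.flatnonzero(y == c) for c in classes}
    if m_samples is None:
        sampled = np.arange(m_total)
    else:
        if m_samples < 1:
            raise ValueError("m_samples must be >= 1")
        rng = np.random.default_rng(random_state)
        sampled = rng.integers(0, m_total, size=m_samples)
    m = sampled.size
    W = np.zeros(p)
    for r in sampled:
        cr = y[r]
        same = members[cr][members[cr] != r]
        hits = same[np.argsort(D[r, same], kind="stable")[:k_neighbors]]
        hit_diff = np.mean(np.abs(X[r] - X[hits]) / denom, axis=0)
        miss_diff = np.zeros(p)
        for c in classes:
            if c == cr:
                continue
            pool = members[c]
            nearest = pool[np.argsort(D[r, pool], kind="stable")[:k_neighbors]]
            weight = priors[c] / (1.0 - priors[cr])
            miss_diff += weight * np.mean(np.abs(X[r] - X[nearest]) / denom, axis=0)
        W += (miss_diff - hit_diff) / m
    return W


class ReliefSelector(_BaseFilterSelector):
    """Relief weighting with a top-n cut (or a weight threshold theta).

    ``theta=None`` (default) ranks by weight and keeps the top n, ties broken
    by ascending index; a float ``theta`` instead keeps every feature with
    W(A) >= theta, whatever their number.
    """

    _method_name = "relief"

    def __init__(
        self,
        n_features_to_select: int = 100,
        m_samples: int | None = None,
        k_neighbors: int = 5,
        theta: float | None = None,
        random_state: int | None = None,
    ) -> None:
        self.n_features_to_select = n_features_to_select
        self.m_samples = m_samples
        self.k_neighbors = k_neighbors
        self.theta = theta
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ReliefSelector":
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        W = relief_weights(
            X, y,
            m_samples=self.m_samples,
            k_neighbors=self.k_neighbors,
            random_state=self.random_state,
        )
        if self.theta is not None:
            selected = [int(i) for i in np.flatnonzero(W >= self.theta)]
        else:
            n = _resolve_n(self.n_features_to_select, X.shape[1])
            selected = _top_n(W, n)
        self._finalize(
            X.shape[1], selected, W,
            {"m_samples": self.m_samples or X.shape[0],
             "k_neighbors": self.k_neighbors, "theta": self.theta},
        )
        return self


# ---------------------------------------------------------------------------
# functional wrappers


def lasso_select(X: np.ndarray, y: np.ndarray, n: int, **config: Any) -> SelectorResult:
    return LassoSelector(n_features_to_select=n, **config).fit(X, y).result()


def ridge_select(X: np.ndarray, y: np.ndarray, n: int, **config: Any) -> SelectorResult:
    return RidgeSelector(n_features_to_select=n, **config).fit(X, y).result()


def mic_select(X: np.ndarray, y: np.ndarray, n: int, **config: Any) -> SelectorResult:
    return MICSelector(n_features_to_select=n, **config).fit(X, y).result()


def relief_select(X: np.ndarray, y: np.ndarray, n: int, **config: Any) -> SelectorResult:
    return ReliefSelector(n_features_to_select=n, **config).fit(X, y).result()
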