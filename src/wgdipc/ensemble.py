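"""LRMR-Ri: the two-stage multi-regression feature selection ensemble.

Stage 1 runs the four single filters (Lasso, Ridge, MIC, Relief), each
selecting n features. If the four selected sets share a common subset (the
four-way intersection, of any size >= 1), that common subset is the optimal
subset and stage 2 is skipped. Otherwise the four sets are pooled into
their union and Ridge re-selects min(n, |union|) features from the pooled
columns — the second stage that gives the ensemble its name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y, check_is_fitted

from .features import FeatureMatrix
from .selectors import (
    LassoSelector,
    MICSelector,
    ReliefSelector,
    RidgeSelector,
    SelectorResult,
)

__all__ = ["EnsembleResult", "LRMRRiSelector", "lrmr_ri", "combine_selections", "apply_selection"]


@dataclass
class EnsembleResult:
    """Stage-1 results plus the ensemble's branch decision and final set."""

    stage1: dict[str, SelectorResult]
    intersection: list[int]
    pooled: list[int]
    stage2_used: bool
    final: list[int]
    diagnostics: dict[str, Any] = field(default_factory=dict)


def combine_selections(
    stage1: Mapping[str, SelectorResult],
    X: np.ndarray,
    y: np.ndarray,
    n: int,
    ridge_params: Mapping[str, Any] | None = None,
) -> EnsembleResult:
    """Apply the two-stage combination rule to four stage-1 selections.

    Kept separate from the stage-1 runs so the branch logic can be exercised
    on constructed selector results.
    """
    sets = [set(res.selected) for res in stage1.values()]
    if len(sets) == 0:
        raise ValueError("no stage-1 selections provided")
    intersection = sorted(set.intersection(*sets))
    pooled = sorted(set.union(*sets))
    if intersection:
        return EnsembleResult(
            stage1=dict(stage1),
            intersection=intersection,
            pooled=pooled,
            stage2_used=False,
            final=list(intersection),
            diagnostics={"branch": "intersection", "pooled_size": len(pooled)},
        )
    if len(pooled) < 2:
        raise ValueError(f"pooled union has {len(pooled)} features; need at least 2")
    n_stage2 = min(n, len(pooled))
    ridge = RidgeSelector(n_features_to_select=n_stage2, **(ridge_params or {}))
    ridge.fit(np.asarray(X, dtype=float)[:, pooled], y)
    final = sorted(pooled[j] for j in ridge.selected_)
    return EnsembleResult(
        stage1=dict(stage1),
        intersection=[],
        pooled=pooled,
        stage2_used=True,
        final=final,
        diagnostics={
            "branch": "ridge_on_pool",
            "pooled_size": len(pooled),
            "stage2_lambda": ridge.diagnostics_["lambda"],
        },
    )


class LRMRRiSelector(SelectorMixin, BaseEstimator):
    """The LRMR-Ri ensemble as a scikit-learn selector.

    The four stage-1 filters share one ``random_state``, stream-split per
    filter, so a single seed reproduces the whole ensemble. In the
    intersection branch the final set may be smaller than
    ``n_features_to_select``; in the pooled branch it has exactly
    min(n, |union|) features.
    """

    def __init__(
        self,
        n_features_to_select: int = 100,
        random_state: int | None = None,
        lasso_params: dict[str, Any] | None = None,
        ridge_params: dict[str, Any] | None = None,
        mic_params: dict[str, Any] | None = None,
        relief_params: dict[str, Any] | None = None,
    ) -> None:
        self.n_features_to_select = n_features_to_select
        self.random_state = random_state
        self.lasso_params = lasso_params
        self.ridge_params = ridge_params
        self.mic_params = mic_params
        self.relief_params = relief_params

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LRMRRiSelector":
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        n = self.n_features_to_select
        seed = 0 if self.random_state is None else int(self.random_state)
        streams = np.random.SeedSequence(seed).generate_state(4) % (2**31)
        relief_params = dict(self.relief_params or {})
        relief_params.setdefault("random_state", int(streams[3]))
        stage1_selectors = {
            "lasso": LassoSelector(n_features_to_select=n, **(self.lasso_params or {})),
            "ridge": RidgeSelector(n_features_to_select=n, **(self.ridge_params or {})),
            "mic": MICSelector(n_features_to_select=n, **(self.mic_params or {})),
            "relief": ReliefSelector(n_features_to_select=n, **relief_params),
        }
        stage1: dict[str, SelectorResult] = {}
        for name, sel in stage1_selectors.items():
            try:
                stage1[name] = sel.fit(X, y).result()
            except Exception as exc:
                raise RuntimeError(f"stage-1 selector {name!r} failed: {exc}") from exc
        result = combine_selections(stage1, X, y, n, self.ridge_params)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[result.final] = True
        self.support_ = mask
        self.selected_ = list(result.final)
        self.stage1_results_ = result.stage1
        self.intersection_ = result.intersection
        self.pooled_ = result.pooled
        self.stage2_used_ = result.stage2_used
        self.ensemble_result_ = result
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


def lrmr_ri(
    X: np.ndarray, y: np.ndarray, n: int, seed: int | None = 0, **params: Any
) -> EnsembleResult:
    """Run the full two-stage ensemble and return its :class:`EnsembleResult`."""
    sel = LRMRRiSelector(n_features_to_select=n, random_state=seed, **params)
    sel.fit(X, y)
    return sel.ensemble_result_


def apply_selection(matrix: FeatureMatrix, indices: list[int]) -> FeatureMatrix:
    """Column-subset a FeatureMatrix, preserving names in index order."""
    return matrix.subset_columns(indices)
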