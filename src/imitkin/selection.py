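"""Feature selection: SVM weights, leave-one-parameter-out, PCA, combined.

Three importance rankings over the 40 condition-block SD features, plus the
combined rule used for the final feature set:

* **SVM weights** — absolute hyperplane weights of a linear SVM (C chosen by
  inner grid search) on the standardized training matrix; top 8.
* **Leave-one-parameter-out (LOPO)** — drop in leave-one-out NB accuracy when
  one feature is removed, relative to the all-features baseline; top 10.
* **PCA** — each feature's share of the first principal component's absolute
  loadings on the standardized matrix; top 3 (top 6 when used standalone).
* **Combined** — (top-8 SVM weight) union (top-3 PCA intersect top-10 LOPO);
  yields between 8 and 11 features.

When selection runs inside an outer cross-validation loop, per-iteration
selected sets are tallied into cross-iteration occurrence counts; the final
reported set is the top-m (default 9) by occurrence.

All indices are 1-based global feature indices; ties break by ascending
index everywhere, making every ranking deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .classifiers import (
    grid_search_svm,
    nb_lopo_accuracies,
    svm_train,
    zscore_apply,
    zscore_fit,
)

__all__ = [
    "RankingResult",
    "SelectionTrace",
    "rank_by_svm_weights",
    "lopo_impact",
    "pca_first_pc_contrib",
    "combined_select",
    "combine_selected",
    "tally_occurrences",
]

SVM_TOP = 8
LOPO_TOP = 10
PCA_TOP = 3
PCA_STANDALONE_TOP = 6
FINAL_TOP = 9


@dataclass
class RankingResult:
    """Per-feature importance scores of one method, in descending rank order."""

    method: str
    scores: np.ndarray  # aligned with global index 1..d
    ranked_indices: list[int]  # 1-based, descending score, ties by index

    def top(self, k: int) -> list[int]:
        return self.ranked_indices[: min(k, len(self.ranked_indices))]


def _rank(scores: np.ndarray, method: str) -> RankingResult:
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((np.arange(len(scores)), -scores))  # descending, ties ascending idx
    return RankingResult(method=method, scores=scores, ranked_indices=[int(i) + 1 for i in order])


def rank_by_svm_weights(
    X: np.ndarray,
    y: np.ndarray,
    C: float | None = None,
    C_grid: np.ndarray | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> RankingResult:
    """Absolute linear-SVM hyperplane weights as importance scores.

    ``X`` is standardized (unless already), the regularization weight C is
    grid-searched on the given data (or fixed via ``C``), and the fitted
    hyperplane's per-feature |w_j| are the scores.
    """
    X = np.asarray(X, dtype=float)
    if standardize:
        mu, sd = zscore_fit(X)
        X = zscore_apply(X, mu, sd)
    if C is None:
        spec, _ = grid_search_svm(
            X, y, kernel="linear", C_grid=C_grid, inner_folds=inner_folds, seed=seed
        )
    else:
        from .classifiers import SVMSpec

        spec = SVMSpec(kernel="linear", C=C)
    model = svm_train(X, y, spec)
    return _rank(np.abs(model.coef_[0]), "svm_weight")


def lopo_impact(X: np.ndarray, y: np.ndarray) -> RankingResult:
    """Leave-one-parameter-out impact on leave-one-out NB accuracy.

    score_j = baseline accuracy - accuracy without feature j; positive scores
    mark features whose removal hurts, i.e. discriminative ones.  The
    baseline (all-features LOOCV accuracy) is stored on the result as
    ``baseline_accuracy``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("leave-one-parameter-out needs >= 2 features")
    baseline, acc_without = nb_lopo_accuracies(X, y)
    res = _rank(baseline - acc_without, "lopo")
    res.baseline_accuracy = baseline  # type: ignore[attr-defined]
    return res


def pca_first_pc_contrib(
    X: np.ndarray, standardize: bool = True
) -> tuple[RankingResult, np.ndarray]:
    """Per-feature contribution (%) to the first principal component.

    PCA of the standardized matrix; contribution_j = |loading_j| as a share
    of the summed absolute first-PC loadings, in percent.  Also returns the
    explained-variance ratios (normalized to sum to 1 over all components).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA contribution needs n >= 3")
    if standardize:
        mu, sd = zscore_fit(X)
        X = zscore_apply(X, mu, sd)
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance matrix has no principal components")
    pca = PCA()
    pca.fit(X)
    loadings = np.abs(pca.components_[0])
    contrib = 100.0 * loadings / loadings.sum()
    return _rank(contrib, "pca"), pca.explained_variance_ratio_


def combined_select(
    X: np.ndarray,
    y: np.ndarray,
    svm_top: int = SVM_TOP,
    pca_top: int = PCA_TOP,
    lopo_top: int = LOPO_TOP,
    inner_folds: int = 5,
    seed: int = 0,
) -> list[int]:
    """The combined selection rule on training data only.

    Selected set = (top ``svm_top`` by SVM weight) union (top ``pca_top`` by
    first-PC contribution intersect top ``lopo_top`` by LOPO impact).  With
    the defaults the result has between 8 and 11 features; returned sorted
    ascending (1-based global indices).
    """
    svm = rank_by_svm_weights(X, y, inner_folds=inner_folds, seed=seed)
    lopo = lopo_impact(X, y)
    pca, _ = pca_first_pc_contrib(X)
    return combine_selected(svm.top(svm_top), pca.top(pca_top), lopo.top(lopo_top))


def combine_selected(
    svm_top: list[int], pca_top: list[int], lopo_top: list[int]
) -> list[int]:
    """Pure combination rule: SVM top set union (PCA top intersect LOPO top)."""
    return sorted(set(svm_top) | (set(pca_top) & set(lopo_top)))


@dataclass
class SelectionTrace:
    """Per-iteration selected sets and cross-iteration occurrence counts."""

    per_iteration: list[list[int]]
    occurrences: dict[int, int] = field(default_factory=dict)

    def top(self, m: int = FINAL_TOP) -> list[int]:
        """Top-m features by occurrence (ties by ascending index)."""
        ranked = sorted(self.occurrences.items(), key=lambda kv: (-kv[1], kv[0]))
        return [idx for idx, _ in ranked[:m]]


def tally_occurrences(per_iteration: list[list[int]]) -> SelectionTrace:
    """Occurrence counts of features over per-iteration selected sets."""
    if not per_iteration:
        raise ValueError("need at least one iteration")
    counts: dict[int, int] = {}
    for sel in per_iteration:
        for idx in set(sel):
            counts[idx] = counts.get(idx, 0) + 1
    return SelectionTrace(per_iteration=[sorted(s) for s in per_iteration], occurrences=counts)
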