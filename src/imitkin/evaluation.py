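"""Two-layer (nested) leave-one-out evaluation.

The outer loop holds out one participant per iteration; everything else —
feature standardization, feature selection, and hyper-parameter grid search
(by stratified inner cross-validation on the remaining participants) — sees
only the training side.  The model is then refit on all training
participants with the chosen features/parameters and predicts the single
held-out one.  Aggregate accuracy is computed from the n held-out
predictions alone, so a correct implementation scores at chance on
label-permuted data: that leakage property is the design's central contract
and is asserted by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import (
    EvalResult,
    GaussianNB,
    SVMSpec,
    compute_metrics,
    forest_fit,
    grid_search_svm,
    round_half_up,
    svm_train,
    tree_fit,
    zscore_apply,
    zscore_fit,
)
from .io import FeatureMatrix
from .selection import (
    PCA_STANDALONE_TOP,
    SelectionTrace,
    combined_select,
    lopo_impact,
    pca_first_pc_contrib,
    rank_by_svm_weights,
    tally_occurrences,
)

__all__ = [
    "SELECTORS",
    "CLASSIFIERS",
    "NestedCVConfig",
    "NestedCVResult",
    "nested_loocv",
    "compare_selection_methods",
    "evaluate_final_features",
]

SELECTORS: tuple[str, ...] = ("svm_weight", "lopo", "pca", "combined", "none")
CLASSIFIERS: tuple[str, ...] = ("nb", "svm_linear", "svm_rbf", "tree", "forest")


@dataclass
class NestedCVConfig:
    """Configuration of one nested leave-one-out run."""

    selector: str = "combined"
    classifier: str = "svm_linear"
    inner_folds: int = 5
    seed: int = 0
    C_grid: np.ndarray | None = None
    gamma_grid: np.ndarray | None = None
    n_trees: int = 500

    def __post_init__(self) -> None:
        if self.selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}, got {self.selector!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}, got {self.classifier!r}")
        if not 2 <= self.inner_folds:
            raise ValueError("inner_folds must be >= 2")


@dataclass
class NestedCVResult:
    """Held-out predictions, per-iteration choices and aggregate metrics."""

    predictions: np.ndarray
    labels: np.ndarray
    selected_per_iteration: list[list[int]]
    hyperparameters: list[SVMSpec | None]
    metrics: EvalResult
    trace: SelectionTrace
    config: NestedCVConfig

    @property
    def accuracy(self) -> float:
        """Held-out accuracy as a fraction in [0, 1]."""
        return float((self.predictions == self.labels).mean())


def _select(X: np.ndarray, y: np.ndarray, cfg: NestedCVConfig, fold_seed: int) -> list[int]:
    if cfg.selector == "none":
        return list(range(1, X.shape[1] + 1))
    if cfg.selector == "svm_weight":
        return sorted(
            rank_by_svm_weights(
                X, y, C_grid=cfg.C_grid, inner_folds=cfg.inner_folds, seed=fold_seed,
                standardize=False,
            ).top(8)
        )
    if cfg.selector == "lopo":
        return sorted(lopo_impact(X, y).top(10))
    if cfg.selector == "pca":
        return sorted(pca_first_pc_contrib(X, standardize=False)[0].top(PCA_STANDALONE_TOP))
    return combined_select(X, y, inner_folds=cfg.inner_folds, seed=fold_seed)


def _fit_predict(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    cfg: NestedCVConfig,
    fold_seed: int,
) -> tuple[int, SVMSpec | None]:
    if cfg.classifier == "nb":
        model = GaussianNB().fit(Xtr, ytr)
        return int(model.predict(Xte)[0]), None
    if cfg.classifier in ("svm_linear", "svm_rbf"):
        kernel = "linear" if cfg.classifier == "svm_linear" else "rbf"
        spec, _ = grid_search_svm(
            Xtr, ytr, kernel=kernel, C_grid=cfg.C_grid, gamma_grid=cfg.gamma_grid,
            inner_folds=cfg.inner_folds, seed=fold_seed,
        )
        model = svm_train(Xtr, ytr, spec)
        return int(model.predict(Xte)[0]), spec
    if cfg.classifier == "tree":
        return int(tree_fit(Xtr, ytr, seed=fold_seed).predict(Xte)[0]), None
    return int(forest_fit(Xtr, ytr, seed=fold_seed, n_trees=cfg.n_trees).predict(Xte)[0]), None


def nested_loocv(fm: FeatureMatrix, cfg: NestedCVConfig | None = None) -> NestedCVResult:
    """Nested leave-one-out cross-validation with in-fold feature selection.

    Per outer iteration: standardize on the training participants, run the
    configured selector on the (standardized) training matrix, grid-search
    hyper-parameters by stratified inner CV, refit on the full training side
    and predict the held-out participant.  The held-out sample influences
    nothing.  Reproducible: per-fold seeds derive from ``cfg.seed`` and the
    outer index.
    """
    cfg = cfg or NestedCVConfig()
    X, y = fm.values, fm.y
    n = len(y)
    if n < 3 or len(np.unique(y)) < 2:
        raise ValueError("need n >= 3 with both classes present")

    preds = np.empty(n, dtype=int)
    selected_all: list[list[int]] = []
    hypers: list[SVMSpec | None] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr_raw, ytr = X[mask], y[mask]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"outer fold {i}: training side is single-class")
        mu, sd = zscore_fit(Xtr_raw)
        Xtr = zscore_apply(Xtr_raw, mu, sd)
        Xte = zscore_apply(X[i : i + 1], mu, sd)
        fold_seed = (cfg.seed * 1009 + i) % (2**31 - 1)

        selected = _select(Xtr, ytr, cfg, fold_seed)
        cols = [s - 1 for s in selected]
        pred, spec = _fit_predict(Xtr[:, cols], ytr, Xte[:, cols], cfg, fold_seed)
        preds[i] = pred
        selected_all.append(selected)
        hypers.append(spec)

    trace = tally_occurrences(selected_all)
    return NestedCVResult(
        predictions=preds,
        labels=y.copy(),
        selected_per_iteration=selected_all,
        hyperparameters=hypers,
        metrics=compute_metrics(preds, y),
        trace=trace,
        config=cfg,
    )


def compare_selection_methods(
    fm: FeatureMatrix,
    methods: tuple[str, ...] = ("svm_weight", "lopo", "pca"),
    classifiers: tuple[str, ...] = ("svm_rbf", "svm_linear", "nb"),
    inner_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Nested-LOOCV accuracy (%) for every (selection method, classifier) pair.

    Rows are methods plus a per-classifier ``average`` row of the 1-dp cells.
    """
    if not methods or not classifiers:
        raise ValueError("need at least one method and one classifier")
    table = pd.DataFrame(index=list(methods), columns=list(classifiers), dtype=float)
    for m in methods:
        for c in classifiers:
            cfg = NestedCVConfig(selector=m, classifier=c, inner_folds=inner_folds, seed=seed)
            table.loc[m, c] = 100.0 * nested_loocv(fm, cfg).accuracy
    table = table.round(1)
    table.loc["average"] = table.mean(axis=0).round(1)
    return table


def evaluate_final_features(
    fm: FeatureMatrix,
    feature_set: list[int],
    classifiers: tuple[str, ...] = CLASSIFIERS,
    inner_folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
    C_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Leave-one-out sensitivity/specificity/accuracy on a fixed feature set.

    Each classifier is evaluated by plain LOOCV on the chosen columns (SVM
    hyper-parameters still grid-searched inside each training fold); an
    ``Avg.`` row of column means at report precision is appended.
    """
    if not feature_set:
        raise ValueError("feature set must be non-empty")
    bad = [f for f in feature_set if not 1 <= f <= fm.n_features]
    if bad:
        raise IndexError(f"feature indices out of range 1..{fm.n_features}: {bad}")
    cols = [f - 1 for f in sorted(set(feature_set))]
    sub = FeatureMatrix(
        values=fm.values[:, cols],
        labels=fm.labels.copy(),
        columns=[fm.columns[c] for c in cols],
        participants=list(fm.participants),
    )
    rows = {}
    for c in classifiers:
        cfg = NestedCVConfig(
            selector="none", classifier=c, inner_folds=inner_folds, seed=seed,
            n_trees=n_trees, C_grid=C_grid, gamma_grid=gamma_grid,
        )
        res = nested_loocv(sub, cfg)
        rows[c] = res.metrics.rounded()
    df = pd.DataFrame(rows, index=["sensitivity", "specificity", "accuracy"]).T
    df.loc["Avg."] = df.mean(axis=0).map(round_half_up)
    return df
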