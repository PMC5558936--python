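"""Classification models and confusion-matrix metrics.

Five models are used throughout: Gaussian Naive Bayes, linear and RBF
support-vector machines, an information-gain decision tree and a random
forest.  The Gaussian NB is implemented here directly — its closed-form
class-conditional densities admit fully vectorised leave-one-out and
leave-one-feature-out evaluation, which the condition screen, the
leave-one-parameter-out selector and the permutation nulls lean on heavily.
SVMs, trees and forests are scikit-learn estimators behind thin wrappers.

Labels are encoded 0/1 with 1 = ASC, the positive class of every metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "GaussianNB",
    "SVMSpec",
    "EvalResult",
    "zscore_fit",
    "zscore_apply",
    "nb_log_joint_loocv",
    "nb_loocv",
    "nb_lopo_accuracies",
    "svm_train",
    "grid_search_svm",
    "tree_fit",
    "forest_fit",
    "compute_metrics",
]

#: Default exhaustive grids (the standard coarse grid-search recommendation).
DEFAULT_C_GRID: np.ndarray = 2.0 ** np.arange(-5, 16, 2)
DEFAULT_GAMMA_GRID: np.ndarray = 2.0 ** np.arange(-15, 4, 2)

_VAR_SMOOTHING = 1e-9  # variance floor as a fraction of the largest feature variance


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with halves away from zero (report convention: 81.25 -> 81.3)."""
    scale = 10.0**ndigits
    return float(np.floor(np.abs(x) * scale + 0.5) / scale * np.sign(x))


def zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and SD for standardization; constant columns get SD 1."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def zscore_apply(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mu) / sd


class GaussianNB:
    """Gaussian Naive Bayes for binary 0/1 labels (1 = ASC).

    Class-conditional densities are independent per-feature Gaussians with
    maximum-likelihood means/variances; variances are floored by
    ``1e-9 * max(per-feature variance of the training data)``.  Prediction
    maximises log prior + sum of log densities; exact ties go to class 0
    (control), the conservative choice.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNB":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("training set must contain both classes (0 and 1)")
        eps = max(_VAR_SMOOTHING * X.var(axis=0).max(), 1e-12)  # guard constant data
        self.theta_ = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
        self.var_ = np.stack([X[y == c].var(axis=0) + eps for c in (0, 1)])
        self.class_count_ = np.array([(y == 0).sum(), (y == 1).sum()])
        self.class_prior_ = self.class_count_ / len(y)
        return self

    def log_joint(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) array of log prior + log likelihood per class."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ll = -0.5 * (
            np.log(2.0 * np.pi * self.var_)[None, :, :]
            + (X[:, None, :] - self.theta_[None, :, :]) ** 2 / self.var_[None, :, :]
        ).sum(axis=2)
        return ll + np.log(self.class_prior_)[None, :]

    def predict(self, X: np.ndarray) -> np.ndarray:
        lj = self.log_joint(X)
        return (lj[:, 1] > lj[:, 0]).astype(int)


def nb_log_joint_loocv(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold NB evidence for every leave-one-out fold, fully vectorised.

    For each held-out sample i, the NB model is (implicitly) refit on the
    remaining n-1 samples via rank-one downdates of the per-class sums and
    sums of squares.  Returns ``(contrib, log_prior)`` where ``contrib`` has
    shape (n, 2, d) — the log density of sample i's feature j under its
    fold's class-c Gaussian — and ``log_prior`` has shape (n, 2).  Dropping a
    feature from the model is then just dropping its slice, which makes
    leave-one-parameter-out evaluation O(n d) total.

    NB posteriors are invariant to per-feature affine standardization (the
    Jacobian factor is common to both classes), so no scaling is applied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, d = X.shape
    counts = np.array([(y == 0).sum(), (y == 1).sum()])
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 members for leave-one-out NB")

    S = np.stack([X[y == c].sum(axis=0) for c in (0, 1)])  # (2, d)
    SS = np.stack([(X[y == c] ** 2).sum(axis=0) for c in (0, 1)])

    # Fold statistics: class c stats lose sample i only when y_i == c.
    own = np.zeros((n, 2), dtype=bool)
    own[np.arange(n), y] = True
    cnt = counts[None, :] - own  # (n, 2)
    S_f = S[None, :, :] - np.where(own[:, :, None], X[:, None, :], 0.0)
    SS_f = SS[None, :, :] - np.where(own[:, :, None], X[:, None, :] ** 2, 0.0)
    mean = S_f / cnt[:, :, None]
    var = SS_f / cnt[:, :, None] - mean**2
    var = np.maximum(var, 0.0)

    # Variance floor from the fold's full training data (both classes pooled).
    S_all = X.sum(axis=0)[None, :] - X
    SS_all = (X**2).sum(axis=0)[None, :] - X**2
    mean_all = S_all / (n - 1)
    var_all = SS_all / (n - 1) - mean_all**2
    eps = np.maximum(_VAR_SMOOTHING * var_all.max(axis=1), 1e-12)  # (n,)
    var = var + eps[:, None, None]

    contrib = -0.5 * (
        np.log(2.0 * np.pi * var) + (X[:, None, :] - mean) ** 2 / var
    )
    log_prior = np.log(cnt / (n - 1))
    return contrib, log_prior


def _nb_predict_from_evidence(contrib: np.ndarray, log_prior: np.ndarray) -> np.ndarray:
    lj = contrib.sum(axis=2) + log_prior
    return (lj[:, 1] > lj[:, 0]).astype(int)


def nb_loocv(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Leave-one-out NB predictions and accuracy (fraction correct)."""
    contrib, log_prior = nb_log_joint_loocv(X, y)
    preds = _nb_predict_from_evidence(contrib, log_prior)
    return preds, float((preds == y).mean())


def nb_lopo_accuracies(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Baseline LOOCV NB accuracy and the accuracy with each feature removed.

    Returns ``(baseline, acc_without)`` where ``acc_without[j]`` is the
    leave-one-out accuracy of the NB trained on all features except j.
    """
    contrib, log_prior = nb_log_joint_loocv(X, y)
    total = contrib.sum(axis=2)  # (n, 2)
    baseline_preds = ((total + log_prior)[:, 1] > (total + log_prior)[:, 0]).astype(int)
    baseline = float((baseline_preds == np.asarray(y)).mean())

    # (n, 2, d): evidence with feature j's contribution removed
    lj = total[:, :, None] - contrib + log_prior[:, :, None]
    preds = (lj[:, 1, :] > lj[:, 0, :]).astype(int)  # (n, d)
    acc_without = (preds == np.asarray(y)[:, None]).mean(axis=0)
    return baseline, acc_without


@dataclass(frozen=True)
class SVMSpec:
    """Kernel and hyper-parameters of one SVM configuration."""

    kernel: str = "linear"
    C: float = 1.0
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("rbf kernel requires gamma > 0")


def svm_train(X: np.ndarray, y: np.ndarray, spec: SVMSpec) -> SVC:
    """Fit a soft-margin SVM; linear models expose ``.coef_`` weights."""
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    kwargs = {} if spec.kernel == "linear" else {"gamma": spec.gamma}
    model = SVC(kernel=spec.kernel, C=spec.C, **kwargs)
    model.fit(X, y)
    return model


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "linear",
    C_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
    inner_folds: int = 5,
    seed: int = 0,
) -> tuple[SVMSpec, float]:
    """Exhaustive (C, gamma) search by stratified inner-CV accuracy.

    Every grid point is evaluated; ties break toward smaller C, then smaller
    gamma (grids are traversed in ascending order and replaced only on a
    strict improvement).  Returns the winning spec and its inner accuracy.
    """
    C_grid = np.sort(np.asarray(DEFAULT_C_GRID if C_grid is None else C_grid, dtype=float))
    if len(C_grid) == 0:
        raise ValueError("C grid must be non-empty")
    if kernel == "rbf":
        gamma_grid = np.sort(
            np.asarray(DEFAULT_GAMMA_GRID if gamma_grid is None else gamma_grid, dtype=float)
        )
        if len(gamma_grid) == 0:
            raise ValueError("gamma grid must be non-empty")
        gammas: list[float | None] = list(gamma_grid)
    else:
        gammas = [None]

    y = np.asarray(y, dtype=int)
    n_splits = min(inner_folds, int(np.bincount(y, minlength=2).min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    best: tuple[SVMSpec, float] | None = None
    for gamma in gammas:
        for C in C_grid:
            spec = SVMSpec(kernel=kernel, C=float(C), gamma=gamma)
            correct = 0
            for tr, te in folds:
                model = svm_train(X[tr], y[tr], spec)
                correct += int((model.predict(X[te]) == y[te]).sum())
            acc = correct / len(y)
            if best is None or acc > best[1] + 1e-12:
                best = (spec, acc)
    assert best is not None
    return best


def tree_fit(X: np.ndarray, y: np.ndarray, seed: int = 0) -> DecisionTreeClassifier:
    """Information-gain (entropy) decision tree, c4.5-style splitting."""
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = DecisionTreeClassifier(criterion="entropy", random_state=seed)
    model.fit(X, y)
    return model


def forest_fit(
    X: np.ndarray, y: np.ndarray, seed: int = 0, n_trees: int = 500
) -> RandomForestClassifier:
    """Bagged random forest (sqrt(d) features per split), seeded."""
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed
    )
    model.fit(X, y)
    return model


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and the derived diagnostic percentages.

    Sensitivity = 100*TP/P (true-positive rate over ASC samples),
    specificity = 100*TN/N (true-negative rate over controls),
    accuracy = 100*(TP+TN)/(P+N).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / self.positives

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / self.negatives

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.positives + self.negatives)

    def rounded(self) -> tuple[float, float, float]:
        """(sensitivity, specificity, accuracy) at report precision (1 dp)."""
        return (
            round_half_up(self.sensitivity),
            round_half_up(self.specificity),
            round_half_up(self.accuracy),
        )


def compute_metrics(predictions: np.ndarray, labels: np.ndarray) -> EvalResult:
    """Confusion counts of 0/1 predictions against 0/1 labels (1 = ASC)."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    return EvalResult(
        tp=int(((predictions == 1) & (labels == 1)).sum()),
        fp=int(((predictions == 1) & (labels == 0)).sum()),
        tn=int(((predictions == 0) & (labels == 0)).sum()),
        fn=int(((predictions == 0) & (labels == 1)).sum()),
    )
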