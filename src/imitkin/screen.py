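"""Condition screening: leave-one-out Naive Bayes accuracy per condition.

Each of the 8 imitation conditions is scored with three feature groups —
(I) the 20 parameter means, (II) the 20 parameter SDs, (III) both — giving
an 8 x 3 accuracy grid with row (per-condition) and column (per-feature-
group) averages.  A joint run trains on the concatenated SD blocks of two
conditions (the 40-column global-index convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .classifiers import GaussianNB, nb_loocv, round_half_up, zscore_apply, zscore_fit
from .io import FeatureMatrix, slice_matrix
from .synthetic import CONDITION_CODES

__all__ = ["FEATURE_GROUPS", "ScreenTable", "loocv", "screen_conditions", "joint_condition_run"]

#: The three feature groups of the screen: parameter means, SDs, or both.
FEATURE_GROUPS: tuple[str, ...] = ("I", "II", "III")
_GROUP_STAT = {"I": "mean", "II": "sd", "III": "both"}


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    classifier_factory: Callable[[], object] = GaussianNB,
    standardize: bool = True,
) -> tuple[np.ndarray, float]:
    """Generic leave-one-out cross-validation.

    For each sample the classifier from ``classifier_factory`` is fit on the
    remaining n-1 samples (standardized with statistics of those n-1 samples
    only) and predicts the held-out one.  Returns per-sample predictions and
    the fraction correct.  Deterministic for deterministic classifiers.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs n >= 3")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"training fold {i} is single-class")
        if standardize:
            mu, sd = zscore_fit(Xtr)
            Xtr, Xte = zscore_apply(Xtr, mu, sd), zscore_apply(X[i : i + 1], mu, sd)
        else:
            Xte = X[i : i + 1]
        model = classifier_factory()
        model.fit(Xtr, ytr)
        preds[i] = int(model.predict(Xte)[0])
    return preds, float((preds == y).mean())


@dataclass
class ScreenTable:
    """8 x 3 LOOCV-accuracy grid with row/column averages (percent)."""

    accuracy: pd.DataFrame  # index: condition codes, columns: feature groups

    @property
    def row_averages(self) -> pd.Series:
        """Per-condition average over the three feature groups.

        Averages are taken over the unrounded cells and reported at 1 dp with
        halves rounded up (48.75 reports as 48.8).
        """
        return self.accuracy.mean(axis=1).map(round_half_up)

    @property
    def column_averages(self) -> pd.Series:
        """Per-feature-group average over the 8 conditions (1 dp, half-up)."""
        return self.accuracy.mean(axis=0).map(round_half_up)

    def best_conditions(self, k: int = 2) -> list[str]:
        return list(self.row_averages.sort_values(ascending=False).index[:k])

    def to_frame(self) -> pd.DataFrame:
        """Report-precision table: cells at 2 dp, averages at 1 dp."""
        df = self.accuracy.round(2).copy()
        df["Average"] = self.row_averages
        avg = self.column_averages
        avg["Average"] = np.nan
        df.loc["Average"] = avg
        return df


def screen_conditions(fm: FeatureMatrix) -> ScreenTable:
    """Leave-one-out NB accuracy for every condition x feature group.

    ``fm`` must carry all 8 conditions with both statistics (the full
    320-column table).  Accuracies are percentages on the unrounded scale;
    report-precision rounding happens in :meth:`ScreenTable.to_frame`.
    """
    y = fm.y
    grid = pd.DataFrame(index=list(CONDITION_CODES), columns=list(FEATURE_GROUPS), dtype=float)
    for code in CONDITION_CODES:
        for group in FEATURE_GROUPS:
            sub = slice_matrix(fm, [code], _GROUP_STAT[group])
            _, acc = nb_loocv(sub.values, y)
            grid.loc[code, group] = 100.0 * acc
    return ScreenTable(accuracy=grid)


def joint_condition_run(fm: FeatureMatrix) -> float:
    """LOOCV NB accuracy (%) on a joint two-condition SD matrix (40 columns)."""
    if fm.n_features != 40:
        raise ValueError(f"joint run expects a 40-column matrix, got {fm.n_features}")
    _, acc = nb_loocv(fm.values, fm.y)
    return 100.0 * acc
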