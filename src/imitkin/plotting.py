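"""Bar-plot conveniences for feature rankings and occurrence tallies.

Requires matplotlib (optional dependency, ``imitkin[plot]``).
"""

from __future__ import annotations

import numpy as np

from .selection import RankingResult, SelectionTrace

__all__ = ["plot_ranking", "plot_occurrences"]


def plot_ranking(result: RankingResult, ax=None, title: str | None = None):
    """Bar plot of per-feature scores against the 1..d global index."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    d = len(result.scores)
    ax.bar(np.arange(1, d + 1), result.scores, color="steelblue")
    ax.set_xlabel("global feature index")
    ax.set_ylabel({"svm_weight": "|w|", "lopo": "accuracy impact", "pca": "PC1 share (%)"}
                  .get(result.method, "score"))
    ax.set_title(title or f"feature importance ({result.method})")
    return ax


def plot_occurrences(trace: SelectionTrace, ax=None, d: int | None = None):
    """Bar plot of cross-iteration selection occurrences per feature."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    d = d or max(trace.occurrences)
    counts = [trace.occurrences.get(i, 0) for i in range(1, d + 1)]
    ax.bar(np.arange(1, d + 1), counts, color="darkorange")
    ax.set_xlabel("global feature index")
    ax.set_ylabel("occurrences")
    ax.set_title(f"selection occurrences over {len(trace.per_iteration)} iterations")
    return ax
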