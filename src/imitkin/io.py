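"""Participant x feature tables: container, indexing convention, and I/O.

A :class:`FeatureMatrix` holds one row per participant and one column per
(condition, statistic, kinematic parameter) triple.  The canonical on-disk
form is a CSV with a ``PARTICIPANT`` column, a ``LABEL`` column (``ASC`` /
``CTRL``) and self-describing feature headers ``<COND>_<STAT>_P<NN>`` (e.g.
``NTF_SD_P16`` = SD of parameter 16, horizontal max amplitude, in the
No-Target Fast condition).

Within a two-condition SD matrix the global feature index runs 1..40:
indices 1-20 are the first condition's parameters in canonical table order,
21-40 the second condition's.  :func:`index_to_label` maps a global index
back to (condition, parameter name) under that convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .kinematics import PARAMETER_LABELS

__all__ = [
    "STATISTICS",
    "FeatureKey",
    "FeatureMatrix",
    "FeatureTableError",
    "read_feature_table",
    "write_feature_table",
    "slice_matrix",
    "index_to_label",
    "label_to_index",
]

logger = logging.getLogger(__name__)

STATISTICS: tuple[str, ...] = ("mean", "sd")

_LABEL_MAP = {"ASC": "ASC", "CTRL": "control", "CONTROL": "control"}
_HEADER_RE = re.compile(r"^([A-Z]+)_(MEAN|SD)_P(\d{1,2})$")


class FeatureTableError(ValueError):
    """Malformed feature table (unknown columns, non-numeric cells, ...)."""


class FeatureKey(NamedTuple):
    """Identity of one feature column."""

    condition: str
    statistic: str  # "mean" or "sd"
    parameter: int  # 1..20, canonical table order

    @property
    def header(self) -> str:
        return f"{self.condition}_{self.statistic.upper()}_P{self.parameter:02d}"

    @property
    def parameter_name(self) -> str:
        return PARAMETER_LABELS[self.parameter - 1]


@dataclass
class FeatureMatrix:
    """Analysis-ready participants x features matrix with group labels."""

    values: np.ndarray
    labels: np.ndarray  # "ASC" / "control" per row
    columns: list[FeatureKey]
    participants: list[str]
    truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        n, d = self.values.shape
        if len(self.labels) != n or len(self.participants) != n:
            raise FeatureTableError("labels/participants length must match row count")
        if len(self.columns) != d:
            raise FeatureTableError("column index length must match column count")
        if np.isnan(self.values).any():
            raise FeatureTableError("analysis-ready matrix must not contain missing values")
        bad = set(self.labels) - {"ASC", "control"}
        if bad:
            raise FeatureTableError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Binary target: 1 for ASC (positive class), 0 for control."""
        return (self.labels == "ASC").astype(int)

    def column_headers(self) -> list[str]:
        return [k.header for k in self.columns]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_headers())
        df.insert(0, "LABEL", ["ASC" if l == "ASC" else "CTRL" for l in self.labels])
        df.insert(0, "PARTICIPANT", self.participants)
        return df


def _parse_header(name: str, where: str) -> FeatureKey:
    m = _HEADER_RE.match(name)
    if not m:
        raise FeatureTableError(f"unknown column {name!r} in {where}")
    cond, stat, p = m.group(1), m.group(2).lower(), int(m.group(3))
    if not 1 <= p <= 20:
        raise FeatureTableError(f"parameter number out of range in column {name!r}")
    return FeatureKey(cond, stat, p)


def _from_frame(df: pd.DataFrame, where: str) -> FeatureMatrix:
    for required in ("PARTICIPANT", "LABEL"):
        if required not in df.columns:
            raise FeatureTableError(f"missing {required} column in {where}")
    feature_cols = [c for c in df.columns if c not in ("PARTICIPANT", "LABEL")]
    columns = [_parse_header(c, where) for c in feature_cols]

    labels = []
    for i, raw in enumerate(df["LABEL"]):
        key = str(raw).strip().upper()
        if key not in _LABEL_MAP:
            raise FeatureTableError(f"unknown group label {raw!r} at row {i} in {where}")
        labels.append(_LABEL_MAP[key])

    # parse with Python's float (correctly rounded, so CSV round-trips exactly)
    values = np.empty((len(df), len(feature_cols)))
    for jc, c in enumerate(feature_cols):
        for i, cell in enumerate(df[c]):
            if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                values[i, jc] = np.nan
                continue
            try:
                values[i, jc] = float(cell)
            except (TypeError, ValueError):
                raise FeatureTableError(
                    f"non-numeric cell at row {i}, column {c!r} in {where}: {cell!r}"
                ) from None
    keep = ~np.isnan(values).any(axis=1)
    if not keep.all():
        dropped = [str(p) for p in df["PARTICIPANT"][~keep]]
        logger.warning("dropping %d row(s) with missing cells: %s", len(dropped), dropped)
    return FeatureMatrix(
        values=values[keep],
        labels=np.array(labels)[keep],
        columns=columns,
        participants=[str(p) for p in df["PARTICIPANT"][keep]],
    )


def read_feature_table(path: str | Path, layout: str = "canonical_csv") -> FeatureMatrix:
    """Read a participants x features table.

    ``layout='canonical_csv'`` reads the package's CSV dialect.
    ``layout='s1_spreadsheet'`` reads an xlsx workbook whose first worksheet
    carries the same header convention (participant and label columns plus
    ``COND_STAT_PNN`` feature headers); rows with missing cells are dropped
    with a logged report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "canonical_csv":
        df = pd.read_csv(path, dtype=str)
    elif layout == "s1_spreadsheet":
        df = pd.read_excel(path, sheet_name=0, dtype=str)
    else:
        raise ValueError(f"unknown layout {layout!r}; use 'canonical_csv' or 's1_spreadsheet'")
    return _from_frame(df, str(path))


def write_feature_table(fm: FeatureMatrix, path: str | Path) -> None:
    """Write the canonical CSV form (full float precision round-trips)."""
    fm.to_frame().to_csv(path, index=False, float_format="%.17g")


def slice_matrix(
    fm: FeatureMatrix,
    conditions: Sequence[str] | str,
    statistic: str = "both",
) -> FeatureMatrix:
    """Column subset for the given conditions and statistic type.

    Columns come out condition-block by condition-block in canonical
    parameter order (the global-index convention), with means before SDs
    within a block when ``statistic='both'``.
    """
    if isinstance(conditions, str):
        conditions = [conditions]
    if statistic not in ("mean", "sd", "both"):
        raise ValueError("statistic must be 'mean', 'sd' or 'both'")
    wanted_stats = STATISTICS if statistic == "both" else (statistic,)

    available = {k.condition for k in fm.columns}
    missing = [c for c in conditions if c not in available]
    if missing:
        raise KeyError(f"condition(s) {missing} not in table; available: {sorted(available)}")

    pos = {k: i for i, k in enumerate(fm.columns)}
    keys: list[FeatureKey] = []
    for cond in conditions:
        for stat in wanted_stats:
            for p in range(1, 21):
                key = FeatureKey(cond, stat, p)
                if key not in pos:
                    raise KeyError(f"column {key.header} absent from table")
                keys.append(key)
    idx = [pos[k] for k in keys]
    return FeatureMatrix(
        values=fm.values[:, idx],
        labels=fm.labels.copy(),
        columns=keys,
        participants=list(fm.participants),
        truth=dict(fm.truth),
    )


def index_to_label(
    index: int, conditions: tuple[str, str] = ("NTF", "NTE")
) -> tuple[str, str]:
    """Map a 1..40 global index of a two-condition matrix to (condition, name).

    Index k <= 20 is parameter k of the first condition; k > 20 is parameter
    k - 20 of the second, both in canonical table order.
    """
    if not 1 <= index <= 40:
        raise IndexError(f"global index must lie in 1..40, got {index}")
    block, p = divmod(index - 1, 20)
    return conditions[block], PARAMETER_LABELS[p]


def label_to_index(
    condition: str, parameter_name: str, conditions: tuple[str, str] = ("NTF", "NTE")
) -> int:
    """Inverse of :func:`index_to_label`."""
    if condition not in conditions:
        raise KeyError(f"condition {condition!r} not in context {conditions}")
    try:
        p = PARAMETER_LABELS.index(parameter_name)
    except ValueError:
        raise KeyError(f"unknown parameter name {parameter_name!r}") from None
    return conditions.index(condition) * 20 + p + 1
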