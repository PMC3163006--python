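"""Cohort container and CSV I/O.

A cohort is a samples x biomarkers matrix of continuous laboratory values
with a binary class label per sample, coded +1 (syndrome present) / -1
(absent). Values are kept in lab-native units; nothing is normalised.
Missing or non-numeric cells are rejected at load time — for a diagnostic
tool, failing loudly beats silent imputation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

__all__ = [
    "CohortTable",
    "GroupSummary",
    "read_cohort",
    "write_cohort",
    "split_by_label",
    "read_whitelist",
    "write_whitelist",
]


@dataclass
class CohortTable:
    """Named biomarker matrix with per-sample binary labels.

    Attributes
    ----------
    sample_ids : list of str
        Opaque per-sample identifiers (row order).
    feature_names : list of str
        Ordered, unique biomarker names (column order).
    values : ndarray of shape (n_samples, n_features)
        Finite float64 lab values.
    labels : ndarray of shape (n_samples,)
        +1 for the positive (syndrome) class, -1 otherwise.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D samples x features matrix")
        m, f = self.values.shape
        if len(self.sample_ids) != m or len(self.labels) != m:
            raise DataError(
                f"row mismatch: {m} value rows, {len(self.sample_ids)} ids, "
                f"{len(self.labels)} labels"
            )
        if len(self.feature_names) != f:
            raise DataError(
                f"column mismatch: {f} value columns, "
                f"{len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != f:
            raise DataError("feature names must be unique")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value for sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise DataError(f"labels must be +1/-1, found {sorted(bad)}")

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == -1).sum())

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_index(name)]

    def select_features(self, names: list[str]) -> "CohortTable":
        """Restrict to the given features, in the given order."""
        idx = [self.feature_index(n) for n in names]
        return CohortTable(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            values=self.values[:, idx].copy(),
            labels=self.labels.copy(),
        )

    def take(self, rows: np.ndarray) -> "CohortTable":
        """Row subset (fold splitting)."""
        rows = np.asarray(rows)
        return CohortTable(
            sample_ids=[self.sample_ids[i] for i in rows],
            feature_names=list(self.feature_names),
            values=self.values[rows],
            labels=self.labels[rows],
        )

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_negative == 0:
            raise DataError(
                "cohort contains a single class; both +1 and -1 samples are "
                "required for fitting or t-testing"
            )

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        df[label_column] = self.labels
        return df

    def row_mapping(self, i: int) -> dict[str, float]:
        """Feature-name -> value map for one sample (tree prediction input)."""
        return dict(zip(self.feature_names, self.values[i]))


@dataclass(frozen=True)
class GroupSummary:
    """Per-class summary of one biomarker: n, mean, unbiased variance."""

    n: int
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DataError(f"group must have n >= 2 samples, got n={self.n}")
        if self.variance < 0:
            raise DataError(f"negative variance {self.variance}")


def read_cohort(
    path: str | Path | io.TextIOBase,
    label_column: str = "label",
    positive_label: str = "1",
    id_column: str | None = "sample_id",
) -> CohortTable:
    """Load a cohort CSV.

    Expects a header row; comma-separated; decimal point. ``label_column``
    holds the class (any two string values; ``positive_label`` maps to +1,
    everything else to -1). ``id_column``, if present, supplies sample ids;
    otherwise 0-based row numbers are used. All remaining columns must be
    numeric biomarkers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found; columns are "
            f"{list(df.columns)}"
        )
    raw_labels = df[label_column].astype(str)
    labels = np.where(raw_labels == str(positive_label), 1, -1)

    if id_column is not None and id_column in df.columns:
        sample_ids = df[id_column].astype(str).tolist()
        feature_cols = [c for c in df.columns if c not in (label_column, id_column)]
    else:
        sample_ids = [str(i) for i in range(len(df))]
        feature_cols = [c for c in df.columns if c != label_column]

    values = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == "":
                raise DataError(
                    f"missing value at row {sample_ids[i]!r}, column {col!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise DataError(
                    f"non-numeric value {cell!r} at row {sample_ids[i]!r}, "
                    f"column {col!r}"
                ) from None

    table = CohortTable(sample_ids, feature_cols, values, labels)
    table.require_both_classes()
    return table


def write_cohort(
    table: CohortTable,
    path: str | Path | io.TextIOBase,
    label_column: str = "label",
    positive_label: str = "1",
    negative_label: str = "-1",
) -> None:
    """Write a cohort CSV readable by :func:`read_cohort`.

    Values are rendered at 12 significant digits, so finite decimal inputs
    round-trip bit-identically at that precision.
    """
    own = isinstance(path, (str, Path))
    fh = open(path, "w", newline="") if own else path
    try:
        fh.write("sample_id," + ",".join(table.feature_names) + f",{label_column}\n")
        for i in range(table.n_samples):
            cells = [f"{v:.12g}" for v in table.values[i]]
            lab = positive_label if table.labels[i] == 1 else negative_label
            fh.write(",".join([table.sample_ids[i], *cells, lab]) + "\n")
    finally:
        if own:
            fh.close()


def split_by_label(table: CohortTable, feature: str) -> tuple[GroupSummary, GroupSummary]:
    """Per-class (n, mean, unbiased variance) of one biomarker.

    Returns the +1 group first, the -1 group second. Either group smaller
    than 2 is an error: a single observation has no variance estimate.
    """
    x = table.column(feature)
    pos = x[table.labels == 1]
    neg = x[table.labels == -1]
    summaries = []
    for cls, grp in ((+1, pos), (-1, neg)):
        if grp.size < 2:
            raise DataError(
                f"class {cls:+d} has n={grp.size} < 2 samples for feature "
                f"{feature!r}; cannot summarise"
            )
        summaries.append(
            GroupSummary(n=int(grp.size), mean=float(grp.mean()),
                         variance=float(grp.var(ddof=1)))
        )
    return summaries[0], summaries[1]


def read_whitelist(path: str | Path) -> list[str]:
    """Read a feature whitelist: one biomarker name per line, blanks ignored."""
    names = [ln.strip() for ln in Path(path).read_text().splitlines()]
    names = [n for n in names if n]
    if not names:
        raise ConfigurationError(f"whitelist {path} is empty")
    return names


def write_whitelist(names: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(n + "\n" for n in names))
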