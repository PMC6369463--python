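"""Decision tables: loading, validation and min-max normalization.

A decision information system ⟨U, A, D⟩ is a set of samples U described by
continuous conditional attributes A together with one categorical decision
attribute D that partitions U into classes ``{D_1, ..., D_r}``.  Everything
downstream — fuzzy similarity relations, neighborhood granules, the
rough-decision matrix, the entropy measures — operates on the normalized
table produced by this module, so all attribute values are expected to lie
in the unit interval.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DecisionTable",
    "SelectionConfig",
    "InputError",
    "ParseError",
    "ValidationError",
    "read_table",
    "normalize",
]


class InputError(ValueError):
    """A required input (file, column) is missing."""


class ParseError(ValueError):
    """A cell could not be interpreted as a number."""


class ValidationError(ValueError):
    """The table violates a structural invariant (e.g. a single class)."""


@dataclasses.dataclass
class DecisionTable:
    """Samples × attributes matrix plus the decision (class) labels.

    Attributes
    ----------
    values : ndarray of shape (n_samples, n_attributes)
        Conditional attribute values; in ``[0, 1]`` once ``normalized``.
    labels : ndarray of shape (n_samples,)
        Decision attribute, one categorical label per sample.
    attribute_ids : list of str
        Column identifiers for A, in table order.
    class_ids : list
        Decision classes ``D_1, ..., D_r`` ordered by first appearance,
        which fixes the column order of the rough-decision matrix.
    normalized : bool
        True once :func:`normalize` has been applied.
    """

    values: np.ndarray
    labels: np.ndarray
    attribute_ids: list[str]
    class_ids: list
    normalized: bool = False

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    def class_codes(self) -> np.ndarray:
        """Integer class index per sample, following ``class_ids`` order."""
        lookup = {c: j for j, c in enumerate(self.class_ids)}
        return np.array([lookup[c] for c in self.labels], dtype=np.intp)

    def column_indices(self, subset: Sequence[str]) -> np.ndarray:
        """Positions of the attribute identifiers in ``subset``."""
        lookup = {a: j for j, a in enumerate(self.attribute_ids)}
        try:
            return np.array([lookup[a] for a in subset], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise InputError(f"unknown attribute identifier {exc.args[0]!r}") from exc

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any broken invariant."""
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, m = self.values.shape
        if m < 1:
            raise ValidationError("at least one conditional attribute is required")
        if len(self.labels) != n:
            raise ValidationError("labels length does not match sample count")
        if len(self.attribute_ids) != m:
            raise ValidationError("attribute_ids length does not match column count")
        if len(set(self.attribute_ids)) != m:
            raise ValidationError("attribute identifiers must be unique")
        present = pd.unique(self.labels)
        if len(present) < 2:
            raise ValidationError("the decision attribute must have at least 2 classes")
        if set(present) != set(self.class_ids):
            raise ValidationError("class_ids must match the labels present (no empty class)")
        if self.normalized:
            if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
                raise ValidationError("normalized values must lie in [0, 1]")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("attribute values must be finite")


@dataclasses.dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the reduction and its evaluation.

    alpha : fuzzy neighborhood radius in ``[0, 1)``.  Similarity below
        ``alpha`` is cut to zero when granules are formed, filtering weakly
        related sample pairs.
    beta : variable-precision tolerance (bits, ``>= 0``): the conditional
        entropy of an accepted reduct may exceed that of the full attribute
        set by at most ``beta``.
    grid_step : increment of the (alpha, beta) sweep over ``[0, 0.5]``.
    cv_folds : folds for stratified cross-validation.
    knn_k : neighbor count for the KNN classifier.
    rng_seed : seed for the cross-validation shuffle.
    """

    alpha: float = 0.1
    beta: float = 0.25
    grid_step: float = 0.05
    cv_folds: int = 10
    knn_k: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValidationError("alpha must satisfy 0 <= alpha < 1")
        if self.beta < 0.0:
            raise ValidationError("beta must be non-negative")
        if self.grid_step <= 0.0:
            raise ValidationError("grid_step must be positive")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be at least 2")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionConfig":
        """Load a config from a flat YAML mapping; absent keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError(f"config file {path} must contain a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_table(path: str | Path, label_column: str) -> DecisionTable:
    """Read a delimited text file into an (un-normalized) decision table.

    The delimiter is chosen from the file extension: ``.tsv``/``.tab`` are
    tab-separated, anything else comma-separated.  One header row is
    required; every non-label column must be fully numeric (no missing
    values).  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, header=0)
    if label_column not in frame.columns:
        raise InputError(
            f"label column {label_column!r} not found; columns are {list(frame.columns)}"
        )
    attr_cols = [c for c in frame.columns if c != label_column]
    if not attr_cols:
        raise ValidationError("no conditional attribute columns besides the label")

    columns = []
    for col in attr_cols:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            cell = frame[col].iloc[row]
            desc = "blank" if pd.isna(cell) else repr(cell)
            raise ParseError(
                f"non-numeric value ({desc}) in column {col!r}, data row {row + 1}"
            )
        columns.append(numeric.to_numpy(dtype=float))
    values = np.column_stack(columns)

    labels = frame[label_column].to_numpy()
    class_ids = list(pd.unique(labels))
    if len(class_ids) < 2:
        raise ValidationError(
            f"label column {label_column!r} has {len(class_ids)} class; at least 2 required"
        )
    table = DecisionTable(
        values=values,
        labels=labels,
        attribute_ids=[str(c) for c in attr_cols],
        class_ids=class_ids,
        normalized=False,
    )
    table.validate()
    return table


def normalize(table: DecisionTable) -> DecisionTable:
    """Min-max scale each attribute column independently onto ``[0, 1]``.

    ``f(x) = (x - x_min) / (x_max - x_min)`` per column.  A zero-range
    (constant) column carries no discriminating information and the formula
    is undefined for it; it is mapped to all zeros and a warning is issued.
    Labels are unchanged; the operation is idempotent and rank-preserving.
    """
    values = table.values.astype(float, copy=True)
    mins = values.min(axis=0)
    maxs = values.max(axis=0)
    span = maxs - mins
    flat = span == 0
    if flat.any():
        names = [table.attribute_ids[j] for j in np.flatnonzero(flat)]
        warnings.warn(
            f"constant attribute column(s) {names} mapped to all zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_span = np.where(flat, 1.0, span)
    scaled = (values - mins) / safe_span
    scaled[:, flat] = 0.0
    out = DecisionTable(
        values=scaled,
        labels=table.labels.copy(),
        attribute_ids=list(table.attribute_ids),
        class_ids=list(table.class_ids),
        normalized=True,
    )
    out.validate()
    return out
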