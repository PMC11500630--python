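"""Mixed-type data model and missingness bookkeeping.

A :class:`MixedDataset` is a rectangular table (a pandas DataFrame under the
hood) together with a per-column :class:`VariableSchema` declaring the
measurement scale of each variable: ``continuous``, ``semicontinuous``
(a spike at a constant mixed with a continuous part), ``binary``,
``categorical`` or ``count``.  Missingness is tracked by a
:class:`MissingMask`, the binary indicator matrix with entries ``m_ij = 1``
where a cell is missing.  Imputers return a :class:`CompletedDataset` (one
filled copy) or a :class:`MultipleImputationSet` (m filled copies).

Categorical values are stored as string labels, never as integer codes, so
that no imputer can accidentally treat them as ordinal.  All user-facing row
and column indices in reports are 1-based; internal arrays are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

SCALES = ("continuous", "semicontinuous", "binary", "categorical", "count")
NUMERIC_SCALES = ("continuous", "semicontinuous", "count")
CATEGORICAL_SCALES = ("binary", "categorical")


class SchemaError(ValueError):
    """A dataset does not conform to its declared schema."""


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one column: its name, scale and scale-specific extras.

    Parameters
    ----------
    name : str
        Column label.
    scale : str
        One of ``continuous``, ``semicontinuous``, ``binary``,
        ``categorical``, ``count``.
    categories : tuple of str, optional
        Ordered label set; required for binary (exactly 2) and categorical
        (at least 2) variables.
    spike_value : float
        The constant spike of a semicontinuous variable (default 0.0).
    """

    name: str
    scale: str
    categories: tuple[str, ...] | None = None
    spike_value: float = 0.0

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise SchemaError(f"unknown scale {self.scale!r} for {self.name!r}")
        if self.scale == "binary":
            if self.categories is None or len(self.categories) != 2:
                raise SchemaError(f"binary variable {self.name!r} needs exactly 2 categories")
        elif self.scale == "categorical":
            if self.categories is None or len(self.categories) < 2:
                raise SchemaError(f"categorical variable {self.name!r} needs >= 2 categories")
        elif self.categories is not None:
            raise SchemaError(f"{self.scale} variable {self.name!r} must not declare categories")

    @property
    def is_numeric(self) -> bool:
        return self.scale in NUMERIC_SCALES

    @property
    def is_categorical(self) -> bool:
        return self.scale in CATEGORICAL_SCALES


@dataclass
class MixedDataset:
    """A rectangular mixed-type table with a per-column scale declaration.

    ``frame`` holds the values: numeric columns as float64 with NaN as the
    missing sentinel, categorical/binary columns as object-dtype string
    labels with NaN as the sentinel.  ``row_ids`` (the frame index) must be
    unique.
    """

    schema: list[VariableSchema]
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.shape[0] < 1 or self.frame.shape[1] < 1:
            raise SchemaError("dataset must have n >= 1 rows and p >= 1 columns")
        names = [v.name for v in self.schema]
        if list(self.frame.columns) != names:
            raise SchemaError("frame columns do not match schema order")
        if self.frame.index.has_duplicates:
            raise SchemaError("row_ids must be unique")
        self.frame = _coerce_frame(self.frame, self.schema)

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.frame.shape[0]

    @property
    def p(self) -> int:
        return self.frame.shape[1]

    @property
    def row_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def var(self, name: str) -> VariableSchema:
        for v in self.schema:
            if v.name == name:
                return v
        raise KeyError(name)

    def columns_of_scale(self, *scales: str) -> list[str]:
        return [v.name for v in self.schema if v.scale in scales]

    @property
    def continuous_columns(self) -> list[str]:
        return self.columns_of_scale("continuous")

    def copy(self) -> "MixedDataset":
        return MixedDataset(list(self.schema), self.frame.copy())

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write RFC-4180 CSV; missing cells become empty fields."""
        self.frame.to_csv(path, index=True, index_label="row_id", na_rep="")

    @classmethod
    def from_csv(cls, path: str | Path, schema: Sequence[VariableSchema]) -> "MixedDataset":
        """Read a CSV written by :meth:`to_csv` (or any CSV with matching
        columns).  Empty fields and the literal ``NA`` both parse as missing."""
        frame = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False, dtype=object)
        if frame.columns[0] == "row_id":
            frame = frame.set_index("row_id")
            frame.index.name = None
            frame.index = pd.Index(
                [int(x) if str(x).lstrip("-").isdigit() else x for x in frame.index]
            )
        names = [v.name for v in schema]
        missing_cols = set(names) - set(frame.columns)
        if missing_cols:
            raise SchemaError(f"CSV lacks declared columns: {sorted(missing_cols)}")
        return cls(list(schema), frame[names])


def _coerce_frame(frame: pd.DataFrame, schema: Sequence[VariableSchema]) -> pd.DataFrame:
    out = {}
    for v in schema:
        col = frame[v.name]
        if v.is_numeric:
            out[v.name] = pd.to_numeric(col, errors="raise").astype(float)
        else:
            vals = col.astype(object).map(lambda x: np.nan if pd.isna(x) else str(x))
            labels = set(x for x in vals if isinstance(x, str))
            bad = labels - set(v.categories)  # type: ignore[arg-type]
            if bad:
                raise SchemaError(f"column {v.name!r} has undeclared categories {sorted(bad)}")
            out[v.name] = vals
    return pd.DataFrame(out, index=frame.index)[[v.name for v in schema]]


# -- schema files ---------------------------------------------------------

def schema_to_dict(schema: Sequence[VariableSchema]) -> dict:
    d = {}
    for v in schema:
        entry: dict = {"scale": v.scale}
        if v.categories is not None:
            entry["categories"] = list(v.categories)
        if v.scale == "semicontinuous":
            entry["spike_value"] = v.spike_value
        d[v.name] = entry
    return d


def schema_from_dict(d: dict) -> list[VariableSchema]:
    out = []
    for name, entry in d.items():
        cats = entry.get("categories")
        out.append(
            VariableSchema(
                name=name,
                scale=entry["scale"],
                categories=tuple(str(c) for c in cats) if cats is not None else None,
                spike_value=float(entry.get("spike_value", 0.0)),
            )
        )
    return out


def load_schema(path: str | Path) -> list[VariableSchema]:
    """Load a YAML or JSON schema file mapping column name -> scale info."""
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return schema_from_dict(d)


def save_schema(schema: Sequence[VariableSchema], path: str | Path) -> None:
    d = schema_to_dict(schema)
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(d, indent=1))
    else:
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# -- missingness ----------------------------------------------------------

@dataclass
class MissingMask:
    """The indicator matrix M with m_ij = 1 where cell (i, j) is missing."""

    entries: np.ndarray  # (n, p) bool

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=bool)
        if self.entries.ndim != 2:
            raise SchemaError("mask must be 2-dimensional")

    @property
    def per_column_counts(self) -> np.ndarray:
        """M(x_j): number of missing cells per column."""
        return self.entries.sum(axis=0)

    @property
    def n_missing(self) -> int:
        return int(self.entries.sum())

    def column(self, j: int) -> np.ndarray:
        return self.entries[:, j]

    def __or__(self, other: "MissingMask") -> "MissingMask":
        return MissingMask(self.entries | other.entries)


def build_mask(dataset: MixedDataset) -> MissingMask:
    """Indicator matrix of the dataset's missing cells (pure, idempotent)."""
    return MissingMask(dataset.frame.isna().to_numpy())


@dataclass
class CompletedDataset:
    """One imputed copy: a MixedDataset with every cell filled."""

    data: MixedDataset
    source_mask: MissingMask
    method_tag: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.data.frame.isna().any().any():
            raise SchemaError("completed dataset still contains missing cells")
        if self.source_mask.entries.shape != self.data.frame.shape:
            raise SchemaError("mask shape does not match completed data")

    @property
    def frame(self) -> pd.DataFrame:
        return self.data.frame


@dataclass
class MultipleImputationSet:
    """m imputed copies of the same dataset/mask."""

    completions: list[CompletedDataset]

    def __post_init__(self) -> None:
        if len(self.completions) < 1:
            raise SchemaError("need m >= 1 completions")
        ref = self.completions[0]
        for c in self.completions[1:]:
            if c.data.frame.shape != ref.data.frame.shape:
                raise SchemaError("completions disagree in shape")
            if not np.array_equal(c.source_mask.entries, ref.source_mask.entries):
                raise SchemaError("completions disagree in source mask")

    @property
    def m(self) -> int:
        return len(self.completions)

    def __iter__(self):
        return iter(self.completions)

    def __getitem__(self, i: int) -> CompletedDataset:
        return self.completions[i]


def check_preservation(original: MixedDataset, completed: CompletedDataset) -> bool:
    """True iff every observed cell of ``original`` is unchanged in
    ``completed`` and no missing sentinel remains."""
    if original.frame.shape != completed.data.frame.shape:
        raise SchemaError("shape mismatch between original and completed data")
    if [v.scale for v in original.schema] != [v.scale for v in completed.data.schema]:
        raise SchemaError("schema mismatch between original and completed data")
    if completed.data.frame.isna().any().any():
        return False
    obs = ~build_mask(original).entries
    a = original.frame.to_numpy(dtype=object)
    b = completed.data.frame.to_numpy(dtype=object)
    return bool(np.all(a[obs] == b[obs]))


def set_missing(data: MixedDataset, entries: np.ndarray) -> MixedDataset:
    """Return a copy of ``data`` with the cells flagged in ``entries`` set
    to the missing sentinel."""
    out = data.copy()
    arr = out.frame.to_numpy(dtype=object)
    arr[np.asarray(entries, dtype=bool)] = np.nan
    out.frame = pd.DataFrame(arr, index=out.frame.index, columns=out.frame.columns)
    out.frame = _coerce_frame(out.frame, out.schema)
    return out


def fill_dataset(data: MixedDataset, values: dict[str, np.ndarray]) -> MixedDataset:
    """Return a copy of ``data`` whose columns are replaced by ``values``
    (full-length arrays); used by imputers to assemble completions."""
    out = data.copy()
    for name, col in values.items():
        out.frame[name] = col
    out.frame = _coerce_frame(out.frame, out.schema)
    return out
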