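"""Tabular dataset container and delimited-text ingestion.

A :class:`TabularDataset` is the unit every pipeline stage consumes: a
feature table, a response vector and a per-column schema.  Loading is
deliberately strict — rows with missing values are rejected (and counted),
and an alphanumeric entry inside an otherwise numeric column aborts the
load with the offending row named, so that silent coercion can never
contaminate the downstream partition statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ColumnSchema",
    "TabularDataset",
    "SchemaError",
    "LoadError",
    "load_dataset",
    "check_size_guard",
    "MAX_ROWS",
    "MAX_FEATURES",
]

#: Hard problem-size ceiling: datasets must be strictly below this many rows
#: and (post-encoding) feature columns.  Larger inputs exhaust memory during
#: the pairwise-distance stages and are refused outright.
MAX_ROWS = 10_000
MAX_FEATURES = 1_000


class SchemaError(ValueError):
    """The dataset's column structure violates a contract."""


class LoadError(ValueError):
    """A delimited-text file could not be ingested cleanly."""


@dataclass(frozen=True)
class ColumnSchema:
    """Role and type of one column.

    role is one of ``feature``, ``response``, ``identifier``; dtype is
    ``numeric`` or ``categorical``.  For categorical columns ``categories``
    is the ordered list of observed levels.
    """

    name: str
    role: str
    dtype: str
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.role not in {"feature", "response", "identifier"}:
            raise SchemaError(f"unknown column role {self.role!r} for {self.name!r}")
        if self.dtype not in {"numeric", "categorical"}:
            raise SchemaError(f"unknown dtype {self.dtype!r} for {self.name!r}")
        if self.dtype == "categorical":
            cats = self.categories or ()
            if len(cats) == 0:
                raise SchemaError(f"categorical column {self.name!r} has no categories")
            if len(set(cats)) != len(cats):
                raise SchemaError(f"duplicate categories in column {self.name!r}")


@dataclass
class TabularDataset:
    """Feature table + response vector + schema.

    ``features`` keeps the raw (possibly categorical) columns; the ``X``
    property exposes the all-numeric matrix and raises if categorical
    columns have not been encoded yet.  ``meta`` carries side information
    (ground-truth columns, outlier flags, hidden regime labels) used only
    by oracles and reports, never by fitting code.
    """

    features: pd.DataFrame
    y: np.ndarray
    schema: list[ColumnSchema]
    name: str = "dataset"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.features) != len(self.y):
            raise SchemaError(
                f"feature rows ({len(self.features)}) != response length ({len(self.y)})"
            )
        if len(self.y) < 1:
            raise SchemaError("dataset must contain at least one row")
        responses = [c for c in self.schema if c.role == "response"]
        if len(responses) != 1:
            raise SchemaError(f"expected exactly one response column, got {len(responses)}")

    # -- introspection -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def response_schema(self) -> ColumnSchema:
        return next(c for c in self.schema if c.role == "response")

    @property
    def feature_schemas(self) -> list[ColumnSchema]:
        return [c for c in self.schema if c.role == "feature"]

    def categorical_features(self) -> list[ColumnSchema]:
        return [c for c in self.feature_schemas if c.dtype == "categorical"]

    @property
    def X(self) -> np.ndarray:
        """All-numeric feature matrix (float64)."""
        cats = self.categorical_features()
        if cats:
            names = ", ".join(c.name for c in cats)
            raise SchemaError(f"categorical features not yet encoded: {names}")
        return self.features.to_numpy(dtype=np.float64)

    # -- row selection -------------------------------------------------
    def take(self, indices: np.ndarray, name: str | None = None) -> "TabularDataset":
        """Row-subset dataset (positional indices); meta columns follow along."""
        indices = np.asarray(indices)
        meta = {}
        for key, val in self.meta.items():
            arr = np.asarray(val)
            meta[key] = arr[indices] if arr.ndim >= 1 and len(arr) == self.n_rows else val
        return TabularDataset(
            features=self.features.iloc[indices].reset_index(drop=True),
            y=self.y[indices],
            schema=list(self.schema),
            name=name or self.name,
            meta=meta,
        )

    def replace(self, **kwargs) -> "TabularDataset":
        return dataclasses.replace(self, **kwargs)


def _infer_dtype(series: pd.Series) -> str:
    converted = pd.to_numeric(series, errors="coerce")
    return "numeric" if not converted.isna().any() else "categorical"


def load_dataset(
    path: str | Path,
    response: str,
    delimiter: str = ",",
    identifier_columns: tuple[str, ...] = (),
    name: str | None = None,
) -> TabularDataset:
    """Read a delimited text file with a header row into a TabularDataset.

    Column types are inferred: a column whose every non-missing entry parses
    as a float is numeric, anything else categorical.  Rows with missing
    values are dropped and counted (``meta['n_dropped_missing']``).  A column
    that is *mostly* numeric but contains stray alphanumeric entries is
    treated as corrupt and aborts the load, naming the first bad row.

    Parameters
    ----------
    path : file path to the delimited text file.
    response : name of the response column.
    delimiter : field separator, comma by default.
    identifier_columns : columns carried through but excluded from features.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=True)
    if response not in raw.columns:
        raise SchemaError(
            f"response column {response!r} not found; columns are {list(raw.columns)}"
        )

    n_before = len(raw)
    raw = raw.dropna()
    n_dropped = n_before - len(raw)
    if len(raw) == 0:
        raise LoadError(f"{path}: every row contains missing values")

    schema: list[ColumnSchema] = []
    columns: dict[str, object] = {}
    for col in raw.columns:
        role = (
            "response"
            if col == response
            else ("identifier" if col in identifier_columns else "feature")
        )
        series = raw[col]
        dtype = _infer_dtype(series)
        if dtype == "numeric":
            values = pd.to_numeric(series).astype(np.float64)
            columns[col] = values
            schema.append(ColumnSchema(col, role, "numeric"))
        else:
            # Corrupt-numeric detection: if >80% of entries parse as floats,
            # the stragglers are almost certainly typos, not category labels.
            parsed = pd.to_numeric(series, errors="coerce")
            frac_numeric = 1.0 - parsed.isna().mean()
            if frac_numeric > 0.8:
                bad_row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
                bad_val = series.iloc[bad_row]
                raise LoadError(
                    f"column {col!r} looks numeric but row {bad_row} holds "
                    f"non-numeric entry {bad_val!r}; clean the file and retry"
                )
            levels = tuple(dict.fromkeys(series.tolist()))
            columns[col] = series.astype(str)
            schema.append(ColumnSchema(col, role, "categorical", categories=levels))

    frame = pd.DataFrame(columns).reset_index(drop=True)
    resp_schema = next(c for c in schema if c.role == "response")
    y = frame.pop(response).to_numpy()
    for ident in identifier_columns:
        frame.pop(ident, None)
    feat_schema = [c for c in schema if c.role == "feature"]
    ds = TabularDataset(
        features=frame[[c.name for c in feat_schema]],
        y=y,
        schema=feat_schema + [resp_schema],
        name=name or path.stem,
        meta={"n_dropped_missing": n_dropped},
    )
    return ds


def check_size_guard(ds: TabularDataset) -> bool:
    """True iff the dataset is strictly below the 10,000 × 1,000 ceiling.

    The feature count is measured after one-hot expansion (each categorical
    column contributes one column per level), since the expanded matrix is
    what the clustering and model-fitting stages actually hold in memory.
    """
    d = 0
    for col in ds.feature_schemas:
        d += len(col.categories) if col.dtype == "categorical" else 1
    return ds.n_rows < MAX_ROWS and d < MAX_FEATURES
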