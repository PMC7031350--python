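"""Encoding, standardization, class-balance checks and the 80/20 split."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .data import ColumnSchema, SchemaError, TabularDataset

__all__ = [
    "EncodingParams",
    "StandardizationParams",
    "SplitPair",
    "one_hot_encode",
    "check_class_balance",
    "standardize",
    "train_validation_split",
    "DegenerateResponseError",
    "EncodingError",
]


class DegenerateResponseError(ValueError):
    """The response vector carries no usable signal (e.g. a single class)."""


class EncodingError(ValueError):
    """A value outside the fitted category vocabulary was encountered."""


@dataclass
class EncodingParams:
    """Fitted one-hot mapping: categorical column -> ordered level list."""

    categories: dict[str, tuple[str, ...]]

    def encoded_columns(self, column: str) -> list[str]:
        return [f"{column}={lvl}" for lvl in self.categories[column]]

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        """Apply the fitted encoding to new rows; unseen levels are errors."""
        out = {}
        for col in features.columns:
            if col not in self.categories:
                out[col] = pd.to_numeric(features[col])
                continue
            levels = self.categories[col]
            values = features[col].astype(str)
            unseen = sorted(set(values) - set(levels))
            if unseen:
                raise EncodingError(
                    f"column {col!r} holds categories never seen in training: {unseen}"
                )
            for lvl in levels:
                out[f"{col}={lvl}"] = (values == lvl).astype(np.float64)
        return pd.DataFrame(out, index=features.index)


def one_hot_encode(ds: TabularDataset) -> tuple[TabularDataset, EncodingParams]:
    """Expand every categorical feature of c levels into c indicator columns.

    All-numeric datasets pass through unchanged (with an empty mapping).  A
    warning fires when categorical features outnumber 20% of the examples —
    one-hot expansion of such a table bloats the design matrix relative to
    the information it holds.
    """
    cats = ds.categorical_features()
    params = EncodingParams(categories={c.name: tuple(c.categories) for c in cats})
    if not cats:
        return ds, params
    if len(cats) > 0.2 * ds.n_rows:
        warnings.warn(
            f"{len(cats)} categorical features for {ds.n_rows} examples "
            "(>20%); one-hot expansion will be wide relative to the sample",
            stacklevel=2,
        )
    frame = params.transform(ds.features)
    schema: list[ColumnSchema] = []
    for col in ds.feature_schemas:
        if col.dtype == "numeric":
            schema.append(col)
        else:
            schema.extend(
                ColumnSchema(name, "feature", "numeric")
                for name in params.encoded_columns(col.name)
            )
    schema.append(ds.response_schema)
    ordered = [c.name for c in schema if c.role == "feature"]
    return ds.replace(features=frame[ordered], schema=schema), params


def check_class_balance(y: np.ndarray, min_ratio: float) -> tuple[float, bool]:
    """Minority/majority class-count ratio, and whether it clears min_ratio."""
    _, counts = np.unique(np.asarray(y), return_counts=True)
    if len(counts) < 2:
        raise DegenerateResponseError("only one class present; balance is undefined")
    ratio = counts.min() / counts.max()
    return float(ratio), bool(ratio >= min_ratio)


@dataclass
class StandardizationParams:
    """Per-feature centre/scale (population statistics) + dropped columns.

    ``ddof=0`` statistics are used; the convention is recorded here so either
    choice can be reproduced exactly from a serialized report.
    """

    mean: np.ndarray
    scale: np.ndarray
    kept_columns: list[str]
    dropped_columns: list[str] = field(default_factory=list)
    ddof: int = 0

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        X = features[self.kept_columns].to_numpy(dtype=np.float64)
        Z = (X - self.mean) / self.scale
        return pd.DataFrame(Z, columns=self.kept_columns, index=features.index)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "kept_columns": list(self.kept_columns),
            "dropped_columns": list(self.dropped_columns),
            "ddof": self.ddof,
        }


def standardize(ds: TabularDataset) -> tuple[TabularDataset, StandardizationParams]:
    """Centre every feature to mean 0 and scale to standard deviation 1.

    Zero-variance features carry no information and would divide by zero;
    they are dropped with a warning and recorded in the returned params.
    """
    X = ds.X
    names = [c.name for c in ds.feature_schemas]
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    keep = scale > 0.0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    if not keep.any():
        raise SchemaError("every feature has zero variance; nothing to model")
    kept_names = [n for n, k in zip(names, keep) if k]
    params = StandardizationParams(
        mean=mean[keep], scale=scale[keep], kept_columns=kept_names, dropped_columns=dropped
    )
    frame = params.transform(ds.features)
    schema = [c for c in ds.schema if c.role != "feature" or c.name in set(kept_names)]
    return ds.replace(features=frame, schema=schema), params


@dataclass
class SplitPair:
    """Disjoint 80/20 train/validation row split of one dataset."""

    train: TabularDataset
    validation: TabularDataset
    seed: int
    train_indices: np.ndarray
    validation_indices: np.ndarray


def train_validation_split(
    ds: TabularDataset, seed: int, train_fraction: float = 0.8, stratify: bool | None = None
) -> SplitPair:
    """Split rows into training (80%) and validation (20%) subsets.

    Classification responses are stratified so the split cannot manufacture
    class imbalance by chance.  The train size is ``floor(0.8 N)``.
    """
    if ds.n_rows < 5:
        raise SchemaError(f"need at least 5 rows to split 80/20, got {ds.n_rows}")
    if stratify is None:
        stratify = ds.response_schema.dtype == "categorical"
    strat_vector = ds.y if stratify else None
    if stratify:
        _, counts = np.unique(ds.y, return_counts=True)
        if counts.min() < 2:
            raise DegenerateResponseError(
                "a class has fewer than 2 members; stratified splitting is "
                "impossible — reconsider the class set or the imbalance_ratio"
            )
    n_train = int(np.floor(train_fraction * ds.n_rows))
    idx = np.arange(ds.n_rows)
    train_idx, val_idx = train_test_split(
        idx, train_size=n_train, random_state=seed, stratify=strat_vector, shuffle=True
    )
    train_idx = np.sort(train_idx)
    val_idx = np.sort(val_idx)
    return SplitPair(
        train=ds.take(train_idx, name=f"{ds.name}[train]"),
        validation=ds.take(val_idx, name=f"{ds.name}[validation]"),
        seed=seed,
        train_indices=train_idx,
        validation_indices=val_idx,
    )
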