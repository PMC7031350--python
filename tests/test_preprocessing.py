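"""Encoding, standardization, balance checks and the train/validation split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from partwise import (
    ColumnSchema,
    TabularDataset,
    check_class_balance,
    one_hot_encode,
    standardize,
    train_validation_split,
)
from partwise.preprocessing import DegenerateResponseError, EncodingError


def _cat_dataset(values, levels, n_extra_numeric=0):
    cols = {"c": pd.Series(values, dtype=str)}
    schema = [ColumnSchema("c", "feature", "categorical", categories=tuple(levels))]
    for i in range(n_extra_numeric):
        cols[f"x{i}"] = np.arange(len(values), dtype=float)
        schema.append(ColumnSchema(f"x{i}", "feature", "numeric"))
    schema.append(ColumnSchema("y", "response", "numeric"))
    return TabularDataset(
        features=pd.DataFrame(cols), y=np.zeros(len(values)), schema=schema
    )


class TestOneHot:
    def test_three_level_encoding(self):
        ds = _cat_dataset(["A", "C"], ["A", "B", "C"])
        enc, _ = one_hot_encode(ds)
        np.testing.assert_array_equal(enc.X, [[1, 0, 0], [0, 0, 1]])

    def test_all_numeric_identity(self):
        ds = TabularDataset(
            features=pd.DataFrame({"a": [1.0, 2.0]}),
            y=np.array([0.0, 1.0]),
            schema=[ColumnSchema("a", "feature", "numeric"),
                    ColumnSchema("y", "response", "numeric")],
        )
        enc, params = one_hot_encode(ds)
        assert enc.features.equals(ds.features)
        assert params.categories == {}

    def test_warning_when_categorical_columns_exceed_fifth_of_rows(self):
        cols = {
            "c1": pd.Series(["A", "B", "A", "B", "A"]),
            "c2": pd.Series(["B", "A", "B", "A", "B"]),
        }
        schema = [
            ColumnSchema("c1", "feature", "categorical", categories=("A", "B")),
            ColumnSchema("c2", "feature", "categorical", categories=("A", "B")),
            ColumnSchema("y", "response", "numeric"),
        ]
        ds = TabularDataset(features=pd.DataFrame(cols), y=np.zeros(5), schema=schema)
        with pytest.warns(UserWarning, match="20%"):
            enc, _ = one_hot_encode(ds)
        assert enc.n_features == 4  # each 2-level column becomes 2 indicators

    def test_unseen_category_raises(self):
        ds = _cat_dataset(["A", "B"], ["A", "B"])
        _, params = one_hot_encode(ds)
        with pytest.raises(EncodingError, match="'c'.*\\['Z'\\]"):
            params.transform(pd.DataFrame({"c": ["Z"]}))

    def test_each_encoded_block_sums_to_one_per_row(self):
        rng = np.random.default_rng(0)
        values = rng.choice(list("ABC"), size=30)
        ds = _cat_dataset(values, ["A", "B", "C"], n_extra_numeric=1)
        enc, params = one_hot_encode(ds)
        block = enc.features[params.encoded_columns("c")].to_numpy()
        np.testing.assert_array_equal(block.sum(axis=1), np.ones(30))


class TestClassBalance:
    @pytest.mark.parametrize(
        "counts,min_ratio,expected",
        [
            ({"a": 50, "b": 50}, 0.5, (1.0, True)),
            ({"a": 80, "b": 20}, 0.5, (0.25, False)),
            ({"a": 30, "b": 30, "c": 15}, 0.4, (0.5, True)),
        ],
    )
    def test_ratio_and_verdict(self, counts, min_ratio, expected):
        y = np.concatenate([np.full(n, k) for k, n in counts.items()])
        ratio, ok = check_class_balance(y, min_ratio)
        assert ratio == pytest.approx(expected[0])
        assert ok is expected[1]

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateResponseError):
            check_class_balance(np.zeros(10), 0.5)


def _numeric_dataset(X, y=None):
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    names = [f"f{i}" for i in range(X.shape[1])]
    return TabularDataset(
        features=pd.DataFrame(X, columns=names),
        y=np.zeros(len(X)) if y is None else y,
        schema=[ColumnSchema(n, "feature", "numeric") for n in names]
        + [ColumnSchema("y", "response", "numeric")],
    )


class TestStandardize:
    def test_population_sigma_on_1_2_3(self):
        ds = _numeric_dataset([[1.0], [2.0], [3.0]])
        out, params = standardize(ds)
        np.testing.assert_allclose(
            out.X.ravel(), [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )
        assert params.ddof == 0

    def test_constant_column_dropped_and_recorded(self):
        ds = _numeric_dataset(np.column_stack([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        with pytest.warns(UserWarning, match="zero-variance"):
            out, params = standardize(ds)
        assert params.dropped_columns == ["f0"]
        assert out.n_features == 1

    def test_idempotent_to_tolerance(self):
        rng = np.random.default_rng(1)
        ds = _numeric_dataset(rng.normal(3.0, 2.0, size=(50, 3)))
        once, _ = standardize(ds)
        twice, _ = standardize(once)
        np.testing.assert_allclose(once.X, twice.X, atol=1e-9)

    def test_means_zero_sds_one(self):
        rng = np.random.default_rng(2)
        out, _ = standardize(_numeric_dataset(rng.normal(5, 7, size=(40, 4))))
        np.testing.assert_allclose(out.X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.X.std(axis=0), 1.0, atol=1e-9)


class TestSplit:
    def test_sizes_80_20(self):
        ds = _numeric_dataset(np.arange(100.0), y=np.arange(100.0))
        pair = train_validation_split(ds, seed=0, stratify=False)
        assert pair.train.n_rows == 80 and pair.validation.n_rows == 20

    def test_stratified_counts_within_one(self):
        y = np.array(["a"] * 60 + ["b"] * 40)
        ds = TabularDataset(
            features=pd.DataFrame({"x": np.arange(100.0)}),
            y=y,
            schema=[ColumnSchema("x", "feature", "numeric"),
                    ColumnSchema("y", "response", "categorical", categories=("a", "b"))],
        )
        pair = train_validation_split(ds, seed=3)
        _, val_counts = np.unique(pair.validation.y, return_counts=True)
        assert abs(val_counts[0] - 12) <= 1 and abs(val_counts[1] - 8) <= 1

    def test_deterministic_under_seed(self):
        ds = _numeric_dataset(np.arange(50.0), y=np.arange(50.0))
        a = train_validation_split(ds, seed=9, stratify=False)
        b = train_validation_split(ds, seed=9, stratify=False)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    @settings(deadline=None, max_examples=25)
    @given(n=st.integers(5, 200), seed=st.integers(0, 2**16))
    def test_split_partitions_rows_for_every_seed(self, n, seed):
        ds = _numeric_dataset(np.arange(float(n)), y=np.arange(float(n)))
        pair = train_validation_split(ds, seed=seed, stratify=False)
        merged = np.sort(np.concatenate([pair.train_indices, pair.validation_indices]))
        np.testing.assert_array_equal(merged, np.arange(n))

    def test_class_with_one_member_errors(self):
        y = np.array(["a"] * 9 + ["b"])
        ds = TabularDataset(
            features=pd.DataFrame({"x": np.arange(10.0)}),
            y=y,
            schema=[ColumnSchema("x", "feature", "numeric"),
                    ColumnSchema("y", "response", "categorical", categories=("a", "b"))],
        )
        with pytest.raises(DegenerateResponseError):
            train_validation_split(ds, seed=0)
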