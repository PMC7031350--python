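"""Linearity verdicts, OLS baseline and the Ho-Kashyap separability test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from partwise import (
    ColumnSchema,
    RunConfig,
    TabularDataset,
    assess_linearity_classification,
    assess_linearity_regression,
    ho_kashyap_separability,
    train_validation_split,
)
from .oracles import lp_separable


def _regression_split(X, y, seed=0):
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    names = [f"f{i}" for i in range(X.shape[1])]
    ds = TabularDataset(
        features=pd.DataFrame(X, columns=names),
        y=np.asarray(y, dtype=float),
        schema=[ColumnSchema(n, "feature", "numeric") for n in names]
        + [ColumnSchema("y", "response", "numeric")],
    )
    return train_validation_split(ds, seed=seed, stratify=False)


def _classification_split(X, y, seed=0):
    names = [f"f{i}" for i in range(X.shape[1])]
    ds = TabularDataset(
        features=pd.DataFrame(X, columns=names),
        y=np.asarray(y),
        schema=[ColumnSchema(n, "feature", "numeric") for n in names]
        + [ColumnSchema("y", "response", "categorical",
                        categories=tuple(map(str, np.unique(y))))],
    )
    return train_validation_split(ds, seed=seed)


class TestRegressionLinearity:
    def test_exact_line_scores_one(self):
        x = np.linspace(0, 10, 50)
        split = _regression_split(x, 2 * x + 1)
        rep = assess_linearity_regression(split, RunConfig(task="regression",
                                                           metric_of_interest="r2",
                                                           linear_threshold=0.6))
        assert rep.x_linear == pytest.approx(1.0)
        assert rep.verdict == "linear"

    def test_pure_noise_is_non_linear(self):
        rng = np.random.default_rng(11)
        split = _regression_split(rng.normal(size=(200, 3)), rng.normal(size=200))
        rep = assess_linearity_regression(split, RunConfig(task="regression",
                                                           metric_of_interest="r2"))
        assert rep.x_linear < 0.1
        assert rep.verdict == "non_linear"

    def test_rosenbrock_flagged_non_linear_at_09(self, rosenbrock_dataset):
        split = _regression_split(rosenbrock_dataset.X, rosenbrock_dataset.y, seed=1)
        cfg = RunConfig(task="regression", metric_of_interest="r2", linear_threshold=0.9)
        rep = assess_linearity_regression(split, cfg)
        assert rep.verdict == "non_linear"

    def test_duplicated_feature_leaves_r2_unchanged(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 2))
        y = X @ [1.0, -2.0] + rng.normal(0, 0.3, 100)
        cfg = RunConfig(task="regression", metric_of_interest="r2")
        base = assess_linearity_regression(_regression_split(X, y), cfg)
        with pytest.warns(UserWarning, match="rank-deficient"):
            dup = assess_linearity_regression(
                _regression_split(np.column_stack([X, X[:, 0]]), y), cfg
            )
        assert abs(base.x_linear - dup.x_linear) < 1e-6

    def test_verdict_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 2))
        y = X[:, 0] + rng.normal(0, 0.5, 100)
        verdicts = []
        for thr in (0.1, 0.5, 0.9, 0.99):
            cfg = RunConfig(task="regression", metric_of_interest="r2",
                            linear_threshold=thr)
            verdicts.append(assess_linearity_regression(_regression_split(X, y), cfg).verdict)
        # once non_linear at some threshold, never linear at a higher one
        seen_nonlinear = False
        for v in verdicts:
            seen_nonlinear = seen_nonlinear or v == "non_linear"
            if seen_nonlinear:
                assert v == "non_linear"


class TestHoKashyap:
    def test_and_pattern_separable(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 0, 0, 1])
        separable, acc = ho_kashyap_separability(X, y)
        assert separable and acc == 1.0

    def test_xor_pattern_not_separable(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([0, 0, 1, 1])
        separable, _ = ho_kashyap_separability(X, y)
        assert not separable

    def test_distant_blobs_fully_separated(self, blobs_2d):
        X, y = blobs_2d
        separable, acc = ho_kashyap_separability(X, y)
        assert separable and acc == 1.0

    def test_agrees_with_lp_oracle_on_small_2d_fixtures(self):
        """Exhaustive check against exact LP feasibility on ≤8-point sets."""
        rng = np.random.default_rng(0)
        pointsets = [
            np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float),
            np.array([[0, 0], [1, 0], [2, 0], [0, 1], [1, 1], [2, 1]], dtype=float),
        ]
        for _ in range(4):
            pointsets.append(rng.uniform(-1, 1, size=(rng.integers(5, 9), 2)))
        for P in pointsets:
            for bits in itertools.product([0, 1], repeat=len(P)):
                y = np.array(bits)
                if len(np.unique(y)) < 2:
                    continue
                hk, _ = ho_kashyap_separability(P, y, max_iter=100_000)
                assert hk == lp_separable(P, y), (P.tolist(), bits)

    def test_rejects_non_binary_labels(self):
        with pytest.raises(ValueError, match="2 classes"):
            ho_kashyap_separability(np.eye(3), np.array([0, 1, 2]))


class TestClassificationLinearity:
    def test_separable_blobs_verdict_linear(self, blobs_2d):
        X, y = blobs_2d
        cfg = RunConfig(task="classification", metric_of_interest="accuracy",
                        linear_threshold=0.8)
        rep = assess_linearity_classification(_classification_split(X, y), cfg)
        assert rep.verdict == "linear"
        assert rep.x_linear == pytest.approx(1.0)

    def test_replicated_xor_is_non_linear(self):
        base = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        X = np.tile(base, (50, 1))
        y = np.tile([0, 0, 1, 1], 50)
        cfg = RunConfig(task="classification", metric_of_interest="accuracy",
                        linear_threshold=0.8)
        rep = assess_linearity_classification(_classification_split(X, y), cfg)
        assert rep.x_linear <= 0.75 + 1e-9  # best linear rule on XOR
        assert rep.verdict == "non_linear"

    def test_identical_features_score_majority_rate(self):
        X = np.ones((100, 2))
        y = np.array([0] * 70 + [1] * 30)
        cfg = RunConfig(task="classification", metric_of_interest="accuracy")
        rep = assess_linearity_classification(_classification_split(X, y), cfg)
        assert rep.x_linear == pytest.approx(0.7, abs=0.05)
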