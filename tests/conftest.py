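"""Shared fixtures: synthetic datasets and one full forced-partition run.

The expensive two-regime pipeline run is session-scoped so the pipeline,
router and acceptance tests can all interrogate the same result object.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from partwise import (
    RunConfig,
    SyntheticSpec,
    make_dataset,
    run_pipeline,
)


@pytest.fixture(scope="session")
def two_regime_dataset():
    return make_dataset(SyntheticSpec(kind="two_regime", n=400, seed=7))


@pytest.fixture(scope="session")
def two_regime_config():
    return RunConfig(
        task="regression",
        metric_of_interest="r2",
        x_user=0.9,
        linear_threshold=0.9,
        min_subset_fraction=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def two_regime_run(two_regime_dataset, two_regime_config):
    """Full forced-partition pipeline run on the two-regime fixture."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(two_regime_dataset, two_regime_config, force_partition=True)


@pytest.fixture(scope="session")
def rosenbrock_dataset():
    return make_dataset(SyntheticSpec(kind="rosenbrock", n=1000, seed=1))


@pytest.fixture()
def blobs_2d():
    """Two well-separated 2-D Gaussian blobs with binary labels."""
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(0.0, 1.0, (50, 2)), rng.normal(10.0, 1.0, (50, 2))])
    y = np.array([0] * 50 + [1] * 50)
    return X, y
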