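"""Synthetic dataset generators for exercising every pipeline stage.

The generators are pure functions of a :class:`SyntheticSpec` — same spec,
bit-identical dataset — and cover the study conditions the pipeline is
designed around:

* a linear ground truth y = x with 5% proportional Gaussian noise, with
  optional mean-preserving multiplicative α-noise layered on top;
* outlier contamination: n rows of a Gaussian-noise dataset have their
  noise redrawn from a much flatter Gaussian (σ₂ ≫ σ₁);
* the 2-D Rosenbrock surface (a−x)² + b(y−x²)², a=5 b=2, on [0,3]² — a
  canonical mildly non-linear regression benchmark;
* a two-regime mixture: two well-separated 5-D Gaussian blobs, each with
  its own linear response law, which destroys pooled linearity while each
  regime stays exactly linear — the parameter-recovery fixture for the
  partition-and-local-models machinery.

Ground-truth columns, regime labels and outlier flags travel in
``TabularDataset.meta`` so oracle tests can reach them; fitting code never
looks at them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ColumnSchema, TabularDataset

__all__ = [
    "SyntheticSpec",
    "add_alpha_noise",
    "rosenbrock",
    "make_linear_dataset",
    "make_rosenbrock_dataset",
    "make_two_regime_dataset",
    "inject_outliers",
    "make_dataset",
]


@dataclass
class SyntheticSpec:
    """Parameters of the artificial-data generators.

    ``alpha`` is the amplitude of the multiplicative uniform noise in
    [0, 1]; ``sigma1`` the base Gaussian noise scale (default 0.25) and
    ``sigma2`` the outlier scale (default 10·σ₁, and must exceed σ₁);
    ``a``/``b`` the Rosenbrock parameters; ``domain`` the feature rectangle.
    """

    kind: str = "linear"
    n: int = 100
    alpha: float = 0.0
    sigma1: float = 0.25
    sigma2: float | None = None
    n_outliers: int = 0
    a: float = 5.0
    b: float = 2.0
    domain: tuple[float, float] = (0.0, 3.0)
    gaussian_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"linear", "two_regime", "rosenbrock", "noisy", "outliered"}:
            raise ValueError(f"unknown synthetic kind {self.kind!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.sigma2 is None:
            self.sigma2 = 10.0 * self.sigma1
        if not self.sigma2 > self.sigma1 > 0.0:
            raise ValueError("need sigma2 > sigma1 > 0")
        if not 0 <= self.n_outliers <= self.n:
            raise ValueError(f"n_outliers must lie in [0, n], got {self.n_outliers}")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def add_alpha_noise(y_exp: np.ndarray, alpha: float, seed: int) -> np.ndarray:
    """Mean-preserving multiplicative noise y·(1 + α(2U − 1)), U ~ Uniform[0,1].

    The multiplier has support exactly [1−α, 1+α] and unit expectation, so
    E(y_noise) = y_exp elementwise.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    y_exp = np.asarray(y_exp, dtype=np.float64)
    u = np.random.default_rng(seed).uniform(0.0, 1.0, size=y_exp.shape)
    return y_exp * (1.0 + alpha * (2.0 * u - 1.0))


def rosenbrock(x, y, a: float = 5.0, b: float = 2.0):
    """Rosenbrock surface (a − x)² + b(y − x²)².

    Minimum valley along the parabola y = x², where the value reduces to
    (a − x)².
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    out = (a - x) ** 2 + b * (y - x**2) ** 2
    return out if out.ndim else float(out)


def _schema(feature_names: list[str]) -> list[ColumnSchema]:
    cols = [ColumnSchema(n, "feature", "numeric") for n in feature_names]
    cols.append(ColumnSchema("y", "response", "numeric"))
    return cols


def make_linear_dataset(spec: SyntheticSpec) -> TabularDataset:
    """Linear ground truth y = x with 5% proportional Gaussian noise.

    The optional α-noise layer multiplies the *already noised* values — the
    uniform layer models measurement-amplitude error on top of the base
    experimental noise.  Ground truth is kept in ``meta['ground_truth']``.
    """
    if spec.n < 10:
        raise ValueError("linear dataset needs n >= 10")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.domain
    x = rng.uniform(lo, hi, size=spec.n)
    truth = x.copy()
    y = truth * (1.0 + rng.normal(0.0, spec.gaussian_noise, size=spec.n))
    if spec.alpha > 0:
        y = add_alpha_noise(y, spec.alpha, seed=spec.seed + 1)
    return TabularDataset(
        features=pd.DataFrame({"x": x}),
        y=y,
        schema=_schema(["x"]),
        name="linear",
        meta={"ground_truth": truth, "spec": spec.to_dict()},
    )


def make_rosenbrock_dataset(spec: SyntheticSpec) -> TabularDataset:
    """Noisy samples of the Rosenbrock surface over the spec's rectangle."""
    if spec.n < 50:
        raise ValueError("rosenbrock dataset needs n >= 50")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.domain
    xy = rng.uniform(lo, hi, size=(spec.n, 2))
    truth = rosenbrock(xy[:, 0], xy[:, 1], spec.a, spec.b)
    y = truth * (1.0 + rng.normal(0.0, spec.gaussian_noise, size=spec.n))
    if spec.alpha > 0:
        y = add_alpha_noise(y, spec.alpha, seed=spec.seed + 1)
    return TabularDataset(
        features=pd.DataFrame({"x1": xy[:, 0], "x2": xy[:, 1]}),
        y=y,
        schema=_schema(["x1", "x2"]),
        name="rosenbrock",
        meta={"ground_truth": truth, "spec": spec.to_dict()},
    )


#: Two-regime geometry: unit-variance 5-D blobs with centres 8σ apart.
_REGIME_SEPARATION = 8.0
_REGIME_DIM = 5
_REGIME_NOISE = 0.1


def make_two_regime_dataset(spec: SyntheticSpec) -> TabularDataset:
    """Two hidden regimes with conflicting linear response laws.

    Two unit-variance 5-D Gaussian blobs sit 8σ apart.  Within each blob
    the response is exactly linear in the blob's *local* (centre-relative)
    coordinates z = x − centre: regime 1 follows y = 2·z₁ + 5 + ε, regime 2
    follows y = −3·z₂ + 5 + ε, ε ~ N(0, 0.1).  Because the slopes act on
    regime-centred coordinates and both regimes share the same baseline,
    the blob offset carries no linear signal about y, so pooled OLS fails
    (R² ≈ 0.45) while each regime alone is fit perfectly — the canonical
    case the recursive partition is built to untangle.  Hidden regime
    labels live in ``meta['regime']``.
    """
    if spec.n % 2 != 0:
        raise ValueError("two-regime dataset needs an even n")
    rng = np.random.default_rng(spec.seed)
    half = spec.n // 2
    Z1 = rng.normal(0.0, 1.0, size=(half, _REGIME_DIM))
    Z2 = rng.normal(0.0, 1.0, size=(half, _REGIME_DIM))
    X1 = Z1
    X2 = Z2 + _REGIME_SEPARATION
    y1 = 2.0 * Z1[:, 0] + 5.0 + rng.normal(0.0, _REGIME_NOISE, size=half)
    y2 = -3.0 * Z2[:, 1] + 5.0 + rng.normal(0.0, _REGIME_NOISE, size=half)
    X = np.vstack([X1, X2])
    y = np.concatenate([y1, y2])
    regime = np.concatenate([np.zeros(half, dtype=int), np.ones(half, dtype=int)])
    perm = rng.permutation(spec.n)
    names = [f"x{i + 1}" for i in range(_REGIME_DIM)]
    return TabularDataset(
        features=pd.DataFrame(X[perm], columns=names),
        y=y[perm],
        schema=_schema(names),
        name="two_regime",
        meta={"regime": regime[perm], "spec": spec.to_dict()},
    )


def inject_outliers(
    ds: TabularDataset,
    n_outliers: int,
    sigma1: float,
    sigma2: float,
    seed: int,
) -> TabularDataset:
    """Convert n random rows into outliers by redrawing their noise.

    The base dataset is assumed built as y = truth + N(0, σ₁) (additive
    Gaussian noise); for each selected row the noise term is *replaced*
    with a fresh draw from the much flatter N(0, σ₂).  Replacement (rather
    than addition) keeps the noisy response centred on the ground truth.
    Flags are stored in ``meta['outlier_mask']``.
    """
    if not sigma2 > sigma1 > 0:
        raise ValueError("need sigma2 > sigma1 > 0")
    if not 0 <= n_outliers <= ds.n_rows:
        raise ValueError(f"n_outliers must lie in [0, {ds.n_rows}], got {n_outliers}")
    if "ground_truth" not in ds.meta:
        raise ValueError("outlier injection needs meta['ground_truth']")
    rng = np.random.default_rng(seed)
    mask = np.zeros(ds.n_rows, dtype=bool)
    y = ds.y.astype(np.float64).copy()
    if n_outliers > 0:
        chosen = rng.choice(ds.n_rows, size=n_outliers, replace=False)
        mask[chosen] = True
        y[chosen] = ds.meta["ground_truth"][chosen] + rng.normal(0.0, sigma2, size=n_outliers)
    out = ds.replace(y=y, meta={**ds.meta, "outlier_mask": mask})
    out.name = f"{ds.name}+outliers"
    return out


def make_outliered_dataset(spec: SyntheticSpec) -> TabularDataset:
    """y = x + N(0, σ₁) with n rows turned into N(0, σ₂) outliers."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.domain
    x = rng.uniform(lo, hi, size=spec.n)
    truth = x.copy()
    y = truth + rng.normal(0.0, spec.sigma1, size=spec.n)
    base = TabularDataset(
        features=pd.DataFrame({"x": x}),
        y=y,
        schema=_schema(["x"]),
        name="outliered",
        meta={"ground_truth": truth, "spec": spec.to_dict()},
    )
    return inject_outliers(base, spec.n_outliers, spec.sigma1, spec.sigma2, seed=spec.seed + 1)


def make_dataset(spec: SyntheticSpec) -> TabularDataset:
    """Dispatch on ``spec.kind``."""
    makers = {
        "linear": make_linear_dataset,
        "noisy": make_linear_dataset,
        "rosenbrock": make_rosenbrock_dataset,
        "two_regime": make_two_regime_dataset,
        "outliered": make_outliered_dataset,
    }
    return makers[spec.kind](spec)
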