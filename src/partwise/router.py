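"""Router classifier, assembled global model, and the final indices.

New examples are predicted in two hops: a *router* — itself a voting
committee of best-per-metric classifiers trained on leaf membership —
assigns each example to a partition leaf, and that leaf's local meta-model
casts the prediction.  The held-out validation split then yields the real
global performance x_modgen, from which the over-fitting index

    IOF = (x̂ − x_modgen) / x_modgen     (per leaf: IOFᵢ = (xᵢ − x_modgen)/x_modgen)

and the improvement over the linear baseline

    I = (x_modgen − x_linear) / x_linear

are computed.  IOF above the tolerance (default 5%) flags the partition as
over-fit and recommends re-partitioning with larger subsets; negative IOF
merely records synergy between the router and the local meta-models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    r2_score,
    recall_score,
)

from .config import RunConfig
from .data import TabularDataset
from .linearity import LinearityReport
from .metamodel import LocalMetaModel, MetaEnsemble, _build_ensemble
from .partitioning import PartitionTree
from .preprocessing import (
    EncodingParams,
    StandardizationParams,
    train_validation_split,
)
from .exploration import explore_models

__all__ = [
    "RouterModel",
    "GlobalModel",
    "EvaluationReport",
    "fit_router",
    "evaluate_global",
    "improvement_index",
    "overfitting_index",
    "score_metric",
]


def improvement_index(x_modgen: float, x_linear: float) -> float:
    """I = (x_modgen − x_linear) / x_linear: relative gain over the linear baseline."""
    if x_linear <= 0:
        raise ValueError("improvement index undefined for a non-positive linear baseline")
    return (x_modgen - x_linear) / x_linear


def overfitting_index(x_hat: float, x_modgen: float) -> float:
    """IOF = (x̂ − x_modgen) / x_modgen: expected minus realised, relative."""
    if x_modgen <= 0:
        raise ValueError("over-fitting index undefined for non-positive realised performance")
    return (x_hat - x_modgen) / x_modgen


def score_metric(metric: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Evaluate one named metric on predictions."""
    if metric == "accuracy":
        return float(accuracy_score(y_true, y_pred))
    if metric == "recall":
        return float(recall_score(y_true, y_pred, average="macro", zero_division=0))
    if metric == "precision":
        return float(precision_score(y_true, y_pred, average="macro", zero_division=0))
    if metric == "f1":
        return float(f1_score(y_true, y_pred, average="macro", zero_division=0))
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if metric == "r2":
        return float(r2_score(y_true, y_pred))
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if metric == "pearson":
            return float(stats.pearsonr(y_true, y_pred).statistic)
        if metric == "kendall":
            return float(stats.kendalltau(y_true, y_pred).statistic)
        if metric == "spearman":
            return float(stats.spearmanr(y_true, y_pred).statistic)
    raise KeyError(f"unknown metric {metric!r}")


@dataclass
class RouterModel:
    """Leaf-assignment classifier: a voting committee over leaf labels."""

    ensemble: MetaEnsemble | None  # None for the single-leaf constant router
    constant_leaf: int | None
    router_metrics: dict[str, float]

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.ensemble is None:
            return np.full(len(X), self.constant_leaf, dtype=int)
        return self.ensemble.predict(X).astype(int)

    def to_dict(self) -> dict:
        return {
            "members": self.ensemble.describe() if self.ensemble else "constant",
            "router_metrics": self.router_metrics,
        }


def fit_router(
    tree: PartitionTree, train: TabularDataset, config: RunConfig, max_attempts: int = 5
) -> RouterModel:
    """Train the classifier that maps feature vectors to partition leaves.

    Training rows are labelled with their leaf id; an inner 80/20 stratified
    sub-split feeds the classification registry (CV on the 80%), the
    best-per-metric winners vote, and the 20% yields the router's own
    accuracy/recall/precision/F1.  If a leaf is missing from the sub-split's
    training side the split is retried with a shifted seed.
    """
    if tree.n_leaves == 1:
        only = tree.leaves[0].node_id
        return RouterModel(ensemble=None, constant_leaf=only,
                           router_metrics={m: 1.0 for m in
                                           ("accuracy", "recall", "precision", "f1")})

    labels = tree.leaf_labels()
    router_cfg = RunConfig(
        task="classification",
        metric_of_interest="accuracy",
        x_user=config.x_user,
        linear_threshold=config.linear_threshold,
        min_subset_fraction=config.min_subset_fraction,
        imbalance_ratio=config.imbalance_ratio,
        iof_threshold=config.iof_threshold,
        max_depth=config.max_depth,
        seed=config.seed,
        cv_folds_policy=config.cv_folds_policy,
    )
    from .data import ColumnSchema

    leaf_ds = TabularDataset(
        features=train.features,
        y=labels,
        schema=[c for c in train.schema if c.role == "feature"]
        + [ColumnSchema("leaf", "response", "categorical",
                        categories=tuple(str(lf.node_id) for lf in tree.leaves))],
        name=f"{train.name}[leaf-labels]",
    )

    last_error: Exception | None = None
    for attempt in range(max_attempts):
        try:
            split = train_validation_split(leaf_ds, seed=config.seed + attempt)
            if set(np.unique(labels)) - set(np.unique(split.train.y)):
                raise ValueError("a leaf is absent from the router training sub-split")
            result = explore_models(split.train, router_cfg)
            ensemble = _build_ensemble(result, split.train, router_cfg)
            pred = ensemble.predict(split.validation.X)
            metrics = {
                m: score_metric(m, split.validation.y, pred)
                for m in ("accuracy", "recall", "precision", "f1")
            }
            return RouterModel(ensemble=ensemble, constant_leaf=None, router_metrics=metrics)
        except ValueError as exc:
            last_error = exc
    raise RuntimeError(
        f"router split failed after {max_attempts} attempts: {last_error}; "
        "consider a larger min_subset_fraction"
    )


@dataclass
class GlobalModel:
    """Router + per-leaf meta-models + the preprocessing needed to feed them."""

    router: RouterModel
    leaf_models: dict[int, LocalMetaModel]
    encoding: EncodingParams
    standardization: StandardizationParams
    config: RunConfig

    def __post_init__(self) -> None:
        if self.router.ensemble is None and self.router.constant_leaf not in self.leaf_models:
            raise ValueError("constant router points at a leaf with no meta-model")

    def _prepare(self, features: pd.DataFrame) -> np.ndarray:
        encoded = self.encoding.transform(features)
        return self.standardization.transform(encoded).to_numpy(dtype=np.float64)

    def predict(self, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Route each raw-feature row to a leaf and apply its meta-model.

        Accepts features in the *training schema* (pre-encoding); returns
        (predictions, assigned leaf ids).
        """
        X = self._prepare(features)
        leaf_ids = self.router.predict(X)
        # router committees can only emit trained leaf ids, but guard anyway
        known = set(self.leaf_models)
        predictions = np.empty(len(X), dtype=object)
        for lid in np.unique(leaf_ids):
            if int(lid) not in known:
                raise KeyError(f"router produced unknown leaf id {lid}")
            mask = leaf_ids == lid
            predictions[mask] = self.leaf_models[int(lid)].predict(X[mask])
        if self.config.task == "regression":
            predictions = predictions.astype(np.float64)
        return predictions, leaf_ids


@dataclass
class EvaluationReport:
    """Every index the pipeline reports, on raw [0,1] scale and in percent."""

    metric_of_interest: str
    x_linear: float
    x_hat: float | None
    x_hat_i: dict[int, float] | None
    x_modgen: float
    iof: float | None
    iof_i: dict[int, float] | None
    improvement: float | None
    per_metric: dict[str, float] = field(default_factory=dict)
    repartition_recommended: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def improvement_percent(self) -> float | None:
        return None if self.improvement is None else round(100 * self.improvement, 1)

    @property
    def iof_percent(self) -> float | None:
        return None if self.iof is None else round(100 * self.iof, 1)

    def to_dict(self) -> dict:
        return {
            "metric_of_interest": self.metric_of_interest,
            "x_linear": self.x_linear,
            "x_hat": self.x_hat,
            "x_hat_i": {str(k): v for k, v in (self.x_hat_i or {}).items()} or None,
            "x_modgen": self.x_modgen,
            "iof": self.iof,
            "iof_percent": self.iof_percent,
            "iof_i": {str(k): v for k, v in (self.iof_i or {}).items()} or None,
            "improvement": self.improvement,
            "improvement_percent": self.improvement_percent,
            "per_metric": self.per_metric,
            "repartition_recommended": self.repartition_recommended,
            "notes": self.notes,
        }


def evaluate_global(
    global_model: GlobalModel,
    validation: TabularDataset,
    linearity: LinearityReport,
    x_hat: float,
    local_models: dict[int, LocalMetaModel] | None = None,
) -> EvaluationReport:
    """Score the assembled model on held-out rows and derive IOF and I.

    ``validation`` must never have touched any fitting step.  The
    re-partition recommendation fires when IOF or any leaf IOFᵢ exceeds the
    configured tolerance; negative values are reported as synergy and
    require no action.
    """
    config = global_model.config
    pred, _ = global_model.predict(validation.features)
    x_modgen = score_metric(config.metric_of_interest, validation.y, pred)
    per_metric = {m: score_metric(m, validation.y, pred) for m in config.metrics}

    iof = overfitting_index(x_hat, x_modgen) if x_modgen > 0 else None
    local_models = local_models or global_model.leaf_models
    iof_i: dict[int, float] = {}
    if x_modgen > 0:
        for lid, lm in local_models.items():
            x_i = lm.local_metrics[config.metric_of_interest]
            iof_i[lid] = overfitting_index(x_i, x_modgen)

    notes: list[str] = []
    recommend = False
    if iof is not None and iof > config.iof_threshold:
        recommend = True
        notes.append(
            f"IOF {100 * iof:.1f}% exceeds the {100 * config.iof_threshold:.0f}% "
            "tolerance: repeat the recursive partition with larger subsets "
            "(raise min_subset_fraction)"
        )
    for lid, v in iof_i.items():
        if v > config.iof_threshold:
            recommend = True
            notes.append(f"leaf {lid}: IOF_i {100 * v:.1f}% exceeds tolerance")
    if iof is not None and iof < 0:
        notes.append("negative IOF: global model outperforms the leaf expectation (synergy)")

    if linearity.x_linear > 0:
        improvement = improvement_index(x_modgen, linearity.x_linear)
    else:
        improvement = None
        notes.append("linear baseline is zero; improvement index undefined")
    x_hat_i = {
        lid: lm.local_metrics[config.metric_of_interest] * lm.size
        for lid, lm in local_models.items()
    }
    total = sum(lm.size for lm in local_models.values())
    x_hat_i = {lid: v / total for lid, v in x_hat_i.items()}

    return EvaluationReport(
        metric_of_interest=config.metric_of_interest,
        x_linear=linearity.x_linear,
        x_hat=x_hat,
        x_hat_i=x_hat_i,
        x_modgen=x_modgen,
        iof=iof,
        iof_i=iof_i,
        improvement=improvement,
        per_metric=per_metric,
        repartition_recommended=recommend,
        notes=notes,
    )
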