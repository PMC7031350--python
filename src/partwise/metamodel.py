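"""Per-leaf meta-models and the size-weighted expected performance x̂.

Inside each partition leaf the model-exploration stage runs again on the
leaf's rows alone; its best-per-metric winners (j ≤ 4 after de-duplication)
are combined into a local meta-model: majority vote for classification
(ties resolved by the member with the best F1), mean prediction for
regression.  The pipeline's headline expectation is then

    x̂ = Σᵢ xᵢ · ℙ(Aᵢ),   ℙ(Aᵢ) = |Aᵢ| / Σⱼ|Aⱼ|,

the probabilistic expected value of the per-leaf performance xᵢ under the
leaf-size distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from sklearn.base import clone
from sklearn.metrics import r2_score

from .config import RunConfig
from .data import TabularDataset
from .exploration import (
    ExplorationResult,
    ModelSpec,
    _classification_fold_scores,
    _correlation,
    cv_folds_for,
    explore_models,
    select_best_per_metric,
)
from .partitioning import PartitionNode

__all__ = [
    "MetaEnsemble",
    "LocalMetaModel",
    "fit_local_metamodel",
    "combine_predictions",
    "weighted_performance",
]


def combine_predictions(
    member_predictions: list[np.ndarray],
    task: str,
    tiebreak_order: list[int] | None = None,
) -> np.ndarray:
    """Combine member predictions: majority vote or mean.

    ``tiebreak_order`` ranks members best-first (by validation F1); on a
    tied vote the prediction of the best-ranked member wins.  With a single
    member the combination is the identity.
    """
    P = np.asarray(member_predictions)
    if task == "regression":
        return P.astype(np.float64).mean(axis=0)
    if P.shape[0] == 1:
        return P[0]
    order = tiebreak_order if tiebreak_order is not None else list(range(P.shape[0]))
    out = np.empty(P.shape[1], dtype=P.dtype)
    for i in range(P.shape[1]):
        votes, counts = np.unique(P[:, i], return_counts=True)
        top = counts.max()
        winners = set(votes[counts == top])
        if len(winners) == 1:
            out[i] = next(iter(winners))
        else:
            # tied vote: defer to the strongest member whose vote is tied
            for member in order:
                if P[member, i] in winners:
                    out[i] = P[member, i]
                    break
    return out


@dataclass
class MetaEnsemble:
    """A fitted committee of up to four best-per-metric models."""

    specs: list[ModelSpec]
    fitted: list[object]
    won_metrics: list[tuple[str, ...]]
    task: str
    tiebreak_order: list[int]

    @property
    def j(self) -> int:
        return len(self.specs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = [m.predict(X) for m in self.fitted]
        return combine_predictions(preds, self.task, self.tiebreak_order)

    def describe(self) -> list[dict]:
        return [
            {"algorithm": s.algorithm, "won_metrics": list(w)}
            for s, w in zip(self.specs, self.won_metrics)
        ]


def _build_ensemble(
    result: ExplorationResult, train: TabularDataset, config: RunConfig
) -> MetaEnsemble:
    members = select_best_per_metric(result)
    specs = [spec for _, spec in members]
    won = [metrics for metrics, _ in members]
    X, y = train.X, train.y
    fitted = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for spec in specs:
            model = clone(spec.build(config.seed))
            model.fit(X, y)
            fitted.append(model)
    # rank members best-first by their F1 (classification) / R² (regression)
    rank_metric = "f1" if config.task == "classification" else "r2"
    strengths = [result.distributions[s.algorithm][rank_metric].score for s in specs]
    order = list(np.argsort(strengths)[::-1])
    return MetaEnsemble(specs=specs, fitted=fitted, won_metrics=won, task=config.task,
                        tiebreak_order=order)


def _cv_combined(
    specs: list[ModelSpec],
    tiebreak_order: list[int],
    train: TabularDataset,
    config: RunConfig,
) -> dict[str, float]:
    """k-fold CV scores of the *combined* predictor on one subset."""
    from sklearn.model_selection import KFold, StratifiedKFold

    X, y = train.X, train.y
    n = train.n_rows
    k = cv_folds_for(n, config.cv_folds_policy)
    if config.task == "classification":
        _, counts = np.unique(y, return_counts=True)
        k = max(2, min(k, int(counts.min())))
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    else:
        y = y.astype(np.float64)
        splitter = KFold(n_splits=min(k, n), shuffle=True, random_state=config.seed)

    fold_scores: dict[str, list[float]] = {m: [] for m in config.metrics}
    oof = np.empty(n, dtype=np.float64 if config.task == "regression" else y.dtype)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr_idx, te_idx in splitter.split(X, y):
            preds = []
            for spec in specs:
                model = clone(spec.build(config.seed))
                model.fit(X[tr_idx], y[tr_idx])
                preds.append(model.predict(X[te_idx]))
            combined = combine_predictions(preds, config.task, tiebreak_order)
            oof[te_idx] = combined
            if config.task == "classification":
                for m, v in _classification_fold_scores(y[te_idx], combined).items():
                    fold_scores[m].append(v)
            else:
                fold_scores["r2"].append(float(r2_score(y[te_idx], combined)))
    scores: dict[str, float] = {}
    for m in config.metrics:
        if config.task == "regression" and m != "r2":
            scores[m] = _correlation(m, y, oof)
        else:
            scores[m] = float(np.mean(fold_scores[m]))
    return scores


@dataclass
class LocalMetaModel:
    """One leaf's fitted meta-model plus its within-leaf CV metrics xᵢ."""

    leaf_id: int
    ensemble: MetaEnsemble
    local_metrics: dict[str, float]
    size: int

    @property
    def combination(self) -> str:
        return "majority_vote" if self.ensemble.task == "classification" else "mean_prediction"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.ensemble.predict(X)

    def to_dict(self) -> dict:
        return {
            "leaf_id": self.leaf_id,
            "size": self.size,
            "members": self.ensemble.describe(),
            "combination": self.combination,
            "local_metrics": self.local_metrics,
        }


def fit_local_metamodel(
    leaf: PartitionNode, train: TabularDataset, config: RunConfig
) -> LocalMetaModel:
    """Explore, select and combine models on one leaf's rows.

    ``local_metrics`` holds the CV scores of the combined predictor (not of
    its best member): the combined model is what predicts in production, so
    it is the one whose expected performance enters x̂.
    """
    subset = train.take(leaf.indices, name=f"{train.name}[leaf{leaf.node_id}]")
    result = explore_models(subset, config)
    ensemble = _build_ensemble(result, subset, config)
    local_metrics = _cv_combined(ensemble.specs, ensemble.tiebreak_order, subset, config)
    return LocalMetaModel(
        leaf_id=leaf.node_id,
        ensemble=ensemble,
        local_metrics=local_metrics,
        size=leaf.size,
    )


def weighted_performance(
    leaves: list[tuple[float, int]]
) -> tuple[float, list[float]]:
    """Size-weighted expected performance over a partition.

    Parameters
    ----------
    leaves : (xᵢ, |Aᵢ|) pairs, one per leaf.

    Returns
    -------
    (x̂, [x̂ᵢ]) where x̂ᵢ = xᵢ·ℙ(Aᵢ) and x̂ = Σ x̂ᵢ = E(x).  The leaf
    probabilities are formed with exact integer ratios before any float
    arithmetic, so Σᵢ ℙ(Aᵢ) = 1 holds exactly.
    """
    if not leaves:
        raise ValueError("weighted performance needs at least one leaf")
    sizes = [int(s) for _, s in leaves]
    if any(s <= 0 for s in sizes):
        raise ValueError(f"leaf sizes must be positive, got {sizes}")
    total = sum(sizes)
    probs = [Fraction(s, total) for s in sizes]
    assert sum(probs) == 1
    x_hat_i = [float(x) * float(p) for (x, _), p in zip(leaves, probs)]
    return float(sum(x_hat_i)), x_hat_i
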