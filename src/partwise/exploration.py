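"""Exploration of mildly non-linear supervised models under cross-validation.

Every registry algorithm is scored with k-fold CV on all four task metrics
(classification: accuracy / macro recall / macro precision / macro F1;
regression: R² / Pearson / Kendall τ / Spearman ρ).  The winner of each
metric is refit on the full training split; de-duplicated winners — at most
four — become the members of a meta-model downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    BaggingClassifier,
    BaggingRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    r2_score,
    recall_score,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .config import RunConfig
from .data import TabularDataset

__all__ = [
    "ModelSpec",
    "MetricDistribution",
    "ExplorationResult",
    "registry_names",
    "make_model",
    "cv_folds_for",
    "explore_models",
    "select_best_per_metric",
    "SubsetTooSmallError",
]


class SubsetTooSmallError(ValueError):
    """Fewer rows than any cross-validation policy row admits."""


#: Default model registries.  Classification spans probability-based
#: (Gaussian naive Bayes), feature-analysis (decision tree), boosting and
#: bagging ensembles, plus distance (KNN) and kernel (RBF SVM) methods;
#: the regression registry holds the direct analogues.  Hyperparameters are
#: the scikit-learn defaults with seeds pinned.
_CLASSIFIERS = {
    "gaussian_nb": lambda seed: GaussianNB(),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(random_state=seed),
    "adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
    "bagging": lambda seed: BaggingClassifier(random_state=seed),
    "gradient_boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(),
    "svm_rbf": lambda seed: SVC(kernel="rbf", random_state=seed),
}
_REGRESSORS = {
    "decision_tree": lambda seed: DecisionTreeRegressor(random_state=seed),
    "random_forest": lambda seed: RandomForestRegressor(random_state=seed),
    "adaboost": lambda seed: AdaBoostRegressor(random_state=seed),
    "bagging": lambda seed: BaggingRegressor(random_state=seed),
    "gradient_boosting": lambda seed: GradientBoostingRegressor(random_state=seed),
    "knn": lambda seed: KNeighborsRegressor(),
    "svm_rbf": lambda seed: SVR(kernel="rbf"),
}


def registry_names(task: str) -> tuple[str, ...]:
    """Ordered algorithm names for a task; the order breaks selection ties."""
    table = _CLASSIFIERS if task == "classification" else _REGRESSORS
    return tuple(table)


def make_model(name: str, task: str, seed: int):
    table = _CLASSIFIERS if task == "classification" else _REGRESSORS
    if name not in table:
        raise KeyError(f"unknown {task} algorithm {name!r}; registry: {tuple(table)}")
    return table[name](seed)


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    task: str
    hyperparameters: tuple = ()

    def build(self, seed: int):
        return make_model(self.algorithm, self.task, seed)


@dataclass
class MetricDistribution:
    """Per-fold scores of one model on one metric.

    ``score`` is the value used for model selection: the fold mean for
    fold-wise metrics, the pooled out-of-fold value for the rank/linear
    correlations (pooling is less noisy than averaging at small n).
    """

    metric: str
    values: list[float]
    score: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=0))


@dataclass
class BestModel:
    metric: str
    spec: ModelSpec
    fitted: object
    score: float


@dataclass
class ExplorationResult:
    distributions: dict[str, dict[str, MetricDistribution]]
    best_per_metric: dict[str, BestModel]
    meets_user_threshold: bool
    metric_of_interest: str
    cv_folds: int
    failures: dict[str, str] = field(default_factory=dict)

    def best_score(self, metric: str) -> float:
        return self.best_per_metric[metric].score

    def to_dict(self) -> dict:
        return {
            "cv_folds": self.cv_folds,
            "meets_user_threshold": self.meets_user_threshold,
            "metric_of_interest": self.metric_of_interest,
            "best_per_metric": {
                m: {"algorithm": b.spec.algorithm, "score": b.score}
                for m, b in self.best_per_metric.items()
            },
            "distributions": {
                model: {m: {"values": d.values, "mean": d.mean, "sd": d.sd, "score": d.score}
                        for m, d in dists.items()}
                for model, dists in self.distributions.items()
            },
            "failures": self.failures,
        }


def cv_folds_for(n: int, policy: tuple[tuple[int, int], ...]) -> int:
    """Fold count for a subset of n rows under a (min_size, k) policy.

    Default policy: 10 folds at n ≥ 100, 5 at n ≥ 50, 3 at n ≥ 6.
    """
    for min_size, k in sorted(policy, reverse=True):
        if n >= min_size:
            return k
    raise SubsetTooSmallError(
        f"{n} rows is below the smallest cross-validatable size "
        f"({min(m for m, _ in policy)})"
    )


def _correlation(kind: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return 0.0  # correlation undefined for constant vectors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if kind == "pearson":
            r = stats.pearsonr(y_true, y_pred).statistic
        elif kind == "kendall":
            r = stats.kendalltau(y_true, y_pred).statistic
        else:
            r = stats.spearmanr(y_true, y_pred).statistic
    return float(0.0 if np.isnan(r) else r)


def _classification_fold_scores(y_true, y_pred) -> dict[str, float]:
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "recall": float(recall_score(y_true, y_pred, average="macro", zero_division=0)),
        "precision": float(precision_score(y_true, y_pred, average="macro", zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
    }


def explore_models(
    train: TabularDataset,
    config: RunConfig,
    algorithms: tuple[str, ...] | None = None,
) -> ExplorationResult:
    """Cross-validate the registry on the training split and pick winners.

    Folds are stratified for classification and shuffled under the config
    seed either way, so repeated runs reproduce the fold scores exactly.
    The per-metric winner is refit on the full training split.  Ties break
    by registry order.
    """
    X = train.X
    y = train.y
    n = train.n_rows
    k = cv_folds_for(n, config.cv_folds_policy)
    names = algorithms or registry_names(config.task)

    if config.task == "classification":
        _, counts = np.unique(y, return_counts=True)
        k = max(2, min(k, int(counts.min())))
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    else:
        y = y.astype(np.float64)
        splitter = KFold(n_splits=min(k, n), shuffle=True, random_state=config.seed)
    folds = list(splitter.split(X, y))

    distributions: dict[str, dict[str, MetricDistribution]] = {}
    failures: dict[str, str] = {}
    for name in names:
        try:
            fold_scores: dict[str, list[float]] = {m: [] for m in config.metrics}
            oof_pred = np.empty(n, dtype=np.float64 if config.task == "regression" else y.dtype)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for tr_idx, te_idx in folds:
                    model = clone(make_model(name, config.task, config.seed))
                    model.fit(X[tr_idx], y[tr_idx])
                    pred = model.predict(X[te_idx])
                    oof_pred[te_idx] = pred
                    if config.task == "classification":
                        for m, v in _classification_fold_scores(y[te_idx], pred).items():
                            fold_scores[m].append(v)
                    else:
                        fold_scores["r2"].append(float(r2_score(y[te_idx], pred)))
                        for m in ("pearson", "kendall", "spearman"):
                            fold_scores[m].append(_correlation(m, y[te_idx], pred))
            dists: dict[str, MetricDistribution] = {}
            for m in config.metrics:
                values = fold_scores[m]
                if config.task == "regression" and m != "r2":
                    score = _correlation(m, y, oof_pred)  # pooled out-of-fold
                else:
                    score = float(np.mean(values))
                dists[m] = MetricDistribution(metric=m, values=values, score=score)
            distributions[name] = dists
        except Exception as exc:  # noqa: BLE001 — diagnostics collected per model
            failures[name] = f"{type(exc).__name__}: {exc}"

    if not distributions:
        raise RuntimeError(f"every model failed to fit; diagnostics: {failures}")

    best_per_metric: dict[str, BestModel] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in config.metrics:
            winner = max(distributions, key=lambda nm: distributions[nm][m].score)
            fitted = clone(make_model(winner, config.task, config.seed))
            fitted.fit(X, y)
            best_per_metric[m] = BestModel(
                metric=m,
                spec=ModelSpec(algorithm=winner, task=config.task),
                fitted=fitted,
                score=distributions[winner][m].score,
            )

    meets = best_per_metric[config.metric_of_interest].score >= config.x_user
    return ExplorationResult(
        distributions=distributions,
        best_per_metric=best_per_metric,
        meets_user_threshold=bool(meets),
        metric_of_interest=config.metric_of_interest,
        cv_folds=k,
        failures=failures,
    )


def select_best_per_metric(result: ExplorationResult) -> list[tuple[tuple[str, ...], ModelSpec]]:
    """Collapse the per-metric winners to unique model specs.

    A model that wins several metrics appears once, tagged with every metric
    it won, so the member count j satisfies 1 ≤ j ≤ 4.
    """
    by_spec: dict[ModelSpec, list[str]] = {}
    for metric, best in result.best_per_metric.items():
        by_spec.setdefault(best.spec, []).append(metric)
    return [(tuple(metrics), spec) for spec, metrics in by_spec.items()]
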