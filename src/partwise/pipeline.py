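"""End-to-end orchestration: load → gates → linearity → exploration →
partition → meta-models → router → evaluation.

The pipeline advances to the next complexity level only when the models
built so far do not meet the user's requirement: a dataset whose best
linear model already clears ``x_user`` stops at the linearity stage; one
whose mildly non-linear exploration winners clear it stops there with a
weighted meta-model (early stop); only a *highly* non-linear dataset — one
failing both — undergoes the recursive binary partition and the full
router + local-meta-model assembly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .data import TabularDataset, check_size_guard
from .exploration import explore_models
from .linearity import assess_linearity
from .metamodel import (
    LocalMetaModel,
    _build_ensemble,
    _cv_combined,
    fit_local_metamodel,
    weighted_performance,
)
from .partitioning import PartitionTree, recursive_partition
from .preprocessing import (
    SplitPair,
    one_hot_encode,
    standardize,
    train_validation_split,
)
from .report import write_report
from .router import (
    GlobalModel,
    evaluate_global,
    fit_router,
    improvement_index,
    overfitting_index,
    score_metric,
)

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("partwise")

STAGES = (
    "loaded",
    "preprocessed",
    "linearity_assessed",
    "explored",
    "partitioned",
    "fitted",
    "evaluated",
)


@dataclass
class PipelineResult:
    """Everything a finished (possibly early-stopped) run produced."""

    stage: str
    early_stop: bool
    config: RunConfig
    linearity: object | None = None
    exploration: object | None = None
    tree: PartitionTree | None = None
    local_models: dict[int, LocalMetaModel] = field(default_factory=dict)
    global_model: GlobalModel | None = None
    evaluation: object | None = None
    split: SplitPair | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "stage": self.stage,
            "early_stop": self.early_stop,
            "linearity": self.linearity.to_dict() if self.linearity else None,
            "exploration": self.exploration.to_dict() if self.exploration else None,
            "partition": self.tree.summary() if self.tree else None,
            "metamodels": {str(k): v.to_dict() for k, v in self.local_models.items()} or None,
            "global": self.evaluation.to_dict() if self.evaluation else None,
        }

    def write(self, path) -> None:
        write_report(self.to_dict(), path)


def _gate(name: str, observed, threshold, decision: str) -> None:
    log.info("gate %-22s observed=%s threshold=%s -> %s", name, observed, threshold, decision)


def run_pipeline(
    dataset: TabularDataset,
    config: RunConfig,
    force_partition: bool = False,
    auto_repartition: bool = False,
    max_repartition_retries: int = 3,
) -> PipelineResult:
    """Run the staged workflow on an in-memory dataset.

    ``force_partition`` skips the early stops and drives the dataset into
    the recursive partition stage regardless of the linearity and
    exploration verdicts (useful for studying the partition itself).

    ``auto_repartition`` acts on the over-fitting recommendation instead of
    merely reporting it: while IOF (or any leaf IOFᵢ) exceeds the
    tolerance, the partition stage is repeated with ``min_subset_fraction``
    raised by 0.05 — larger leaves, fewer of them — up to
    ``max_repartition_retries`` times.
    """
    if not check_size_guard(dataset):
        raise ValueError(
            f"dataset {dataset.name!r} exceeds the 10,000 × 1,000 size ceiling "
            "(rows × post-encoding features); reduce dimensions before running"
        )
    if config.task == "classification" and len(np.unique(dataset.y)) > 5:
        warnings.warn(
            "response has more than 5 categories; the recursive partition's "
            "class-balance gate may degrade performance on such datasets",
            stacklevel=2,
        )

    # preprocessing: split raw rows, then fit encoding/scaling on train only
    split_raw = train_validation_split(dataset, seed=config.seed)
    train_enc, enc_params = one_hot_encode(split_raw.train)
    train_std, std_params = standardize(train_enc)
    val_frame = std_params.transform(enc_params.transform(split_raw.validation.features))
    validation_std = train_std.replace(
        features=val_frame.reset_index(drop=True),
        y=split_raw.validation.y,
        name=f"{dataset.name}[validation]",
        meta={},
    )
    split = SplitPair(
        train=train_std,
        validation=validation_std,
        seed=config.seed,
        train_indices=split_raw.train_indices,
        validation_indices=split_raw.validation_indices,
    )
    result = PipelineResult(stage="preprocessed", early_stop=False, config=config, split=split)

    # stage 1: linearity
    linearity = assess_linearity(split, config)
    result.linearity = linearity
    result.stage = "linearity_assessed"
    _gate("linear_threshold", round(linearity.x_linear, 4), config.linear_threshold,
          linearity.verdict)
    if not force_partition and linearity.verdict == "linear" and linearity.x_linear >= config.x_user:
        from .router import EvaluationReport

        result.early_stop = True
        result.evaluation = EvaluationReport(
            metric_of_interest=config.metric_of_interest,
            x_linear=linearity.x_linear,
            x_hat=None, x_hat_i=None,
            x_modgen=linearity.x_linear,
            iof=None, iof_i=None,
            improvement=0.0,
            notes=[f"linear model ({linearity.best_linear_model}) already meets "
                   f"x_user={config.x_user}; no non-linear modelling required"],
        )
        return result

    # stage 2: exploration of mildly non-linear models
    exploration = explore_models(split.train, config)
    result.exploration = exploration
    result.stage = "explored"
    best = exploration.best_score(config.metric_of_interest)
    _gate("x_user(exploration)", round(best, 4), config.x_user,
          "meets" if exploration.meets_user_threshold else "below")
    if not force_partition and exploration.meets_user_threshold:
        from .router import EvaluationReport

        ensemble = _build_ensemble(exploration, split.train, config)
        cv_scores = _cv_combined(ensemble.specs, ensemble.tiebreak_order, split.train, config)
        pred = ensemble.predict(split.validation.X)
        x_modgen = score_metric(config.metric_of_interest, split.validation.y, pred)
        per_metric = {m: score_metric(m, split.validation.y, pred) for m in config.metrics}
        x_hat = cv_scores[config.metric_of_interest]
        result.early_stop = True
        result.evaluation = EvaluationReport(
            metric_of_interest=config.metric_of_interest,
            x_linear=linearity.x_linear,
            x_hat=x_hat, x_hat_i=None,
            x_modgen=x_modgen,
            iof=overfitting_index(x_hat, x_modgen) if x_modgen > 0 else None,
            iof_i=None,
            improvement=(improvement_index(x_modgen, linearity.x_linear)
                         if linearity.x_linear > 0 else None),
            per_metric=per_metric,
            notes=["exploration winners meet x_user; stopped before partitioning "
                   f"(members: {[s.algorithm for s in ensemble.specs]})"],
        )
        return result

    # stage 3: the dataset is highly non-linear — recursive binary partition
    def partition_and_fit(cfg: RunConfig) -> None:
        tree = recursive_partition(split.train, cfg)
        result.tree = tree
        result.stage = "partitioned"
        _gate("partition", f"{tree.n_leaves} leaves", "-", "accepted")

        local_models: dict[int, LocalMetaModel] = {
            leaf.node_id: fit_local_metamodel(leaf, split.train, cfg)
            for leaf in tree.leaves
        }
        result.local_models = local_models
        result.stage = "fitted"

        x_hat, _ = weighted_performance(
            [(lm.local_metrics[cfg.metric_of_interest], lm.size)
             for lm in local_models.values()]
        )

        router = fit_router(tree, split.train, cfg)
        result.global_model = GlobalModel(
            router=router,
            leaf_models=local_models,
            encoding=enc_params,
            standardization=std_params,
            config=cfg,
        )
        result.evaluation = evaluate_global(
            result.global_model, split_raw.validation, linearity, x_hat, local_models
        )
        result.stage = "evaluated"
        _gate("iof_threshold", result.evaluation.iof, cfg.iof_threshold,
              "repartition" if result.evaluation.repartition_recommended else "ok")

    partition_and_fit(config)
    if auto_repartition:
        cfg = config
        for _ in range(max_repartition_retries):
            if not result.evaluation.repartition_recommended:
                break
            fraction = min(0.5, cfg.min_subset_fraction + 0.05)
            if fraction == cfg.min_subset_fraction:
                break
            cfg = RunConfig.from_dict({**cfg.to_dict(), "min_subset_fraction": fraction})
            log.info("auto re-partition with min_subset_fraction=%.2f", fraction)
            partition_and_fit(cfg)
    return result
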