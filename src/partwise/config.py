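"""Run configuration: the thresholds and seeds that steer every stage."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "CLASSIFICATION_METRICS", "REGRESSION_METRICS"]

CLASSIFICATION_METRICS = ("accuracy", "recall", "precision", "f1")
REGRESSION_METRICS = ("r2", "pearson", "kendall", "spearman")

#: Default fold policy: (minimum subset size, k).  Scanned top-down, first
#: matching row wins.  Ten folds for comfortable sample sizes, coarser
#: folding as subsets shrink.
DEFAULT_CV_POLICY: tuple[tuple[int, int], ...] = ((100, 10), (50, 5), (6, 3))


@dataclass
class RunConfig:
    """User-facing knobs for one end-to-end run.

    Parameters
    ----------
    task : ``classification`` or ``regression``.
    metric_of_interest : the metric the user optimises; must belong to the
        task's metric family.
    x_user : minimum acceptable performance in [0, 1]; stages stop early the
        moment a model clears it.
    linear_threshold : linearity verdict threshold in [0, 1].
    min_subset_fraction : smallest admissible leaf, as a fraction of the
        training rows, in (0, 0.5].
    imbalance_ratio : minimum minority/majority class-count ratio each leaf
        must keep (classification only), in (0, 1].
    iof_threshold : over-fitting tolerance on the IOF index (default 5%).
    max_depth : recursion cap for the binary partition (default 5, at most
        32 leaves).
    seed : master RNG seed; fixing it makes the whole pipeline deterministic.
    cv_folds_policy : (min_size, k) rows mapping subset size to fold count.
    """

    task: str = "classification"
    metric_of_interest: str = "accuracy"
    x_user: float = 0.8
    linear_threshold: float = 0.8
    min_subset_fraction: float = 0.1
    imbalance_ratio: float = 0.25
    iof_threshold: float = 0.05
    max_depth: int = 5
    seed: int = 0
    cv_folds_policy: tuple[tuple[int, int], ...] = field(default=DEFAULT_CV_POLICY)

    def __post_init__(self) -> None:
        if self.task not in {"classification", "regression"}:
            raise ValueError(f"unknown task {self.task!r}")
        family = CLASSIFICATION_METRICS if self.task == "classification" else REGRESSION_METRICS
        if self.metric_of_interest not in family:
            raise ValueError(
                f"metric {self.metric_of_interest!r} not valid for {self.task}; "
                f"choose from {family}"
            )
        for attr in ("x_user", "linear_threshold"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must lie in [0, 1], got {v}")
        if not 0.0 < self.min_subset_fraction <= 0.5:
            raise ValueError(
                f"min_subset_fraction must lie in (0, 0.5], got {self.min_subset_fraction}"
            )
        if not 0.0 < self.imbalance_ratio <= 1.0:
            raise ValueError(f"imbalance_ratio must lie in (0, 1], got {self.imbalance_ratio}")
        if self.max_depth < 0:
            raise ValueError("max_depth must be non-negative")
        self.cv_folds_policy = tuple(
            sorted((tuple(row) for row in self.cv_folds_policy), reverse=True)
        )

    @property
    def metrics(self) -> tuple[str, ...]:
        return CLASSIFICATION_METRICS if self.task == "classification" else REGRESSION_METRICS

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cv_folds_policy"] = [list(row) for row in self.cv_folds_policy]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cv_folds_policy" in d:
            d["cv_folds_policy"] = tuple(tuple(row) for row in d["cv_folds_policy"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON (decided by suffix)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
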