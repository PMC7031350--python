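"""Recursive quality-gated binary partitioning of a training set.

The training rows are split with a binary-search-tree-shaped recursion: at
each node a grid of 2-cluster candidates (k-means over several distance
metrics, Birch over a threshold grid, agglomerative over affinity × linkage
combinations) is proposed, each scored with the silhouette coefficient
(under its own affinity) and the Calinski-Harabasz index.  A candidate is
adopted only if both sides stay above the minimum-cardinality gate, keep
class balance (classification), and its silhouette is positive.  Recursion
continues on both children until no candidate survives or the depth cap is
reached; the resulting leaves form the partition A₁…Aₙ, which is then
statistically validated (Kruskal-Wallis across leaves per feature with
Benjamini-Hochberg control, per-member silhouettes, per-leaf variance
flags).

Clustering sees the standardized feature matrix only — never the response —
so that a router classifier can later assign unlabeled examples to leaves
from features alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, Birch, KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    pairwise_distances,
    silhouette_samples,
    silhouette_score,
)

from .config import RunConfig
from .data import TabularDataset
from .preprocessing import check_class_balance

__all__ = [
    "SplitCandidate",
    "PartitionNode",
    "PartitionTree",
    "PartitionValidationReport",
    "propose_candidates",
    "accept_split",
    "recursive_partition",
    "validate_partition",
    "two_medoids",
]


@dataclass
class SplitCandidate:
    """One proposed bipartition of a node's rows, with its quality scores.

    ``silhouette`` is computed with the Euclidean metric for *every*
    candidate so that scores are commensurable when candidates are ranked
    against each other; ``silhouette_affinity`` is the same statistic under
    the candidate's own affinity (identical for Euclidean candidates) and
    is reported for diagnostics.
    """

    algorithm: str
    parameters: dict
    labels: np.ndarray
    silhouette: float
    silhouette_affinity: float
    calinski_harabasz: float

    @property
    def descriptor(self) -> str:
        params = ",".join(f"{k}={v}" for k, v in sorted(self.parameters.items()))
        return f"{self.algorithm}({params})"

    def summary(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "parameters": self.parameters,
            "silhouette": self.silhouette,
            "silhouette_affinity": self.silhouette_affinity,
            "calinski_harabasz": self.calinski_harabasz,
            "sizes": np.bincount(self.labels).tolist(),
        }


@dataclass
class PartitionNode:
    """Node of the partition tree; a leaf when it has no children."""

    indices: np.ndarray  # positional row indices into the training dataset
    depth: int
    node_id: int
    children: list["PartitionNode"] = field(default_factory=list)
    chosen_candidate: SplitCandidate | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def size(self) -> int:
        return len(self.indices)

    def iter_leaves(self):
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.iter_leaves()

    def summary(self) -> dict:
        out = {"node_id": self.node_id, "depth": self.depth, "size": self.size}
        if self.chosen_candidate is not None:
            out["split"] = self.chosen_candidate.summary()
        if self.children:
            out["children"] = [c.summary() for c in self.children]
        return out


@dataclass
class PartitionValidationReport:
    """Statistical credentials of a finished partition."""

    feature_pvalues: dict[str, float]
    feature_pvalues_adjusted: dict[str, float]
    leaf_mean_silhouette: dict[int, float]
    leaf_positive_silhouette_fraction: dict[int, float]
    leaf_zero_variance_features: dict[int, list[str]]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feature_pvalues": self.feature_pvalues,
            "feature_pvalues_adjusted": self.feature_pvalues_adjusted,
            "leaf_mean_silhouette": {str(k): v for k, v in self.leaf_mean_silhouette.items()},
            "leaf_positive_silhouette_fraction": {
                str(k): v for k, v in self.leaf_positive_silhouette_fraction.items()
            },
            "leaf_zero_variance_features": {
                str(k): v for k, v in self.leaf_zero_variance_features.items()
            },
            "warnings": self.warnings,
        }


@dataclass
class PartitionTree:
    root: PartitionNode
    validation: PartitionValidationReport | None = None

    @property
    def leaves(self) -> list[PartitionNode]:
        return list(self.root.iter_leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_labels(self) -> np.ndarray:
        """Per-row leaf node_id vector over the training rows."""
        labels = np.empty(self.root.size, dtype=int)
        for leaf in self.leaves:
            labels[leaf.indices] = leaf.node_id
        return labels

    def summary(self) -> dict:
        leaves = self.leaves
        return {
            "n_leaves": len(leaves),
            "leaf_sizes": {str(lf.node_id): lf.size for lf in leaves},
            "max_depth": max(lf.depth for lf in leaves),
            "tree": self.root.summary(),
            "validation": self.validation.to_dict() if self.validation else None,
        }

    def to_dot(self) -> str:
        """GraphViz DOT rendering of the tree (nodes annotated with sizes)."""
        lines = ["digraph partition {", "  node [shape=box];"]
        def walk(node: PartitionNode):
            label = f"id={node.node_id}\\nm={node.size}"
            if node.chosen_candidate is not None:
                label += f"\\n{node.chosen_candidate.algorithm}"
                label += f"\\nsil={node.chosen_candidate.silhouette:.3f}"
            lines.append(f'  n{node.node_id} [label="{label}"];')
            for child in node.children:
                lines.append(f"  n{node.node_id} -> n{child.node_id};")
                walk(child)
        walk(self.root)
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# candidate generation


def two_medoids(
    X: np.ndarray, metric: str, seed: int, max_iter: int = 100
) -> np.ndarray:
    """2-cluster k-medoids under an arbitrary distance metric.

    Lloyd-style alternation with medoid updates (the medoid of a cluster is
    the member minimising its summed within-cluster distance), which stays
    well-defined for metrics — Manhattan, cosine — where a coordinate mean
    is not a meaningful centre.  Initialised from the globally farthest pair
    of points, so the procedure is deterministic given the data.
    """
    m = len(X)
    D = pairwise_distances(X, metric=metric)
    # farthest-pair initialisation: maximally spread seeds
    i, j = np.unravel_index(np.argmax(D), D.shape)
    medoids = np.array([i, j])
    labels = np.zeros(m, dtype=int)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in (0, 1):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return labels


def _score_candidate(
    X: np.ndarray, labels: np.ndarray, algorithm: str, parameters: dict, metric: str
) -> SplitCandidate | None:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sil = float(silhouette_score(X, labels, metric="euclidean"))
        sil_aff = (
            sil if metric == "euclidean"
            else float(silhouette_score(X, labels, metric=metric))
        )
        ch = float(calinski_harabasz_score(X, labels))
    return SplitCandidate(
        algorithm=algorithm,
        parameters=parameters,
        labels=labels,
        silhouette=sil,
        silhouette_affinity=sil_aff,
        calinski_harabasz=ch,
    )


def propose_candidates(
    X: np.ndarray, seed: int, min_leaf_size: int = 1
) -> list[SplitCandidate]:
    """Score the full 2-cluster candidate grid on a node's feature matrix.

    Grid: k-means × {euclidean (Lloyd), manhattan, cosine (medoid update)},
    Birch × threshold {0.3, 0.5, 0.7}, agglomerative × affinity {euclidean,
    manhattan, cosine} × linkage {complete, average, single} plus
    ward/euclidean.  Candidates that collapse to a single cluster are
    dropped; each survivor carries a Euclidean silhouette (the comparable
    ranking score), its own-affinity silhouette, and the Calinski-Harabasz
    score.
    """
    m = len(X)
    if m < 2 * min_leaf_size or m < 4:
        return []
    candidates: list[SplitCandidate] = []

    def add(labels, algorithm, parameters, metric):
        cand = _score_candidate(X, labels, algorithm, parameters, metric)
        if cand is not None:
            candidates.append(cand)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        add(
            KMeans(n_clusters=2, random_state=seed, n_init=10).fit_predict(X),
            "kmeans", {"metric": "euclidean"}, "euclidean",
        )
        for metric in ("manhattan", "cosine"):
            if metric == "cosine" and np.any(np.linalg.norm(X, axis=1) == 0):
                continue  # cosine distance undefined at the origin
            add(two_medoids(X, metric, seed), "kmeans", {"metric": metric}, metric)
        for threshold in (0.3, 0.5, 0.7):
            add(
                Birch(n_clusters=2, threshold=threshold).fit_predict(X),
                "birch", {"threshold": threshold}, "euclidean",
            )
        add(
            AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(X),
            "agglomerative", {"affinity": "euclidean", "linkage": "ward"}, "euclidean",
        )
        for affinity in ("euclidean", "manhattan", "cosine"):
            if affinity == "cosine" and np.any(np.linalg.norm(X, axis=1) == 0):
                continue
            for linkage in ("complete", "average", "single"):
                labels = AgglomerativeClustering(
                    n_clusters=2, metric=affinity, linkage=linkage
                ).fit_predict(X)
                add(labels, "agglomerative", {"affinity": affinity, "linkage": linkage}, affinity)
    return candidates


# ---------------------------------------------------------------------------
# gates and recursion


def accept_split(
    candidate: SplitCandidate,
    node: PartitionNode,
    y: np.ndarray,
    config: RunConfig,
    n_total: int,
) -> bool:
    """Apply the cardinality, class-balance and cluster-quality gates.

    Both sides must hold at least ``min_subset_fraction`` of the *total*
    training rows; for classification each side must also keep every class
    represented at the configured imbalance ratio; and the candidate's
    silhouette must be positive (a non-positive silhouette means the split
    is no better than leaving the rows together).
    """
    sizes = np.bincount(candidate.labels, minlength=2)
    if sizes.min() == 0:
        return False
    min_size = config.min_subset_fraction * n_total
    if sizes.min() < min_size:
        return False
    if candidate.silhouette <= 0.0:
        return False
    if config.task == "classification":
        y_node = y[node.indices]
        for side in (0, 1):
            y_side = y_node[candidate.labels == side]
            if len(np.unique(y_side)) < 2:
                return False
            _, ok = check_class_balance(y_side, config.imbalance_ratio)
            if not ok:
                return False
    return True


def recursive_partition(train: TabularDataset, config: RunConfig) -> PartitionTree:
    """Grow the quality-gated binary partition of the training rows.

    Depth-first: at each node the candidate grid is ranked by silhouette
    (ties: higher Calinski-Harabasz, then grid order) and the best candidate
    passing :func:`accept_split` is adopted; the node becomes a leaf when no
    candidate survives or the depth cap is hit.  A root with no admissible
    split yields a single-leaf tree — the caller then falls back to one
    global meta-model.
    """
    X = train.X
    y = train.y
    n_total = train.n_rows
    min_leaf = max(1, int(np.ceil(config.min_subset_fraction * n_total)))
    counter = [0]

    def next_id() -> int:
        counter[0] += 1
        return counter[0] - 1

    def grow(indices: np.ndarray, depth: int) -> PartitionNode:
        node = PartitionNode(indices=indices, depth=depth, node_id=next_id())
        if depth >= config.max_depth or len(indices) < 2 * min_leaf:
            return node
        candidates = propose_candidates(X[indices], seed=config.seed, min_leaf_size=min_leaf)
        ranked = sorted(
            enumerate(candidates),
            key=lambda pair: (-pair[1].silhouette, -pair[1].calinski_harabasz, pair[0]),
        )
        for _, cand in ranked:
            if accept_split(cand, node, y, config, n_total):
                node.chosen_candidate = cand
                left = indices[cand.labels == 0]
                right = indices[cand.labels == 1]
                node.children = [grow(left, depth + 1), grow(right, depth + 1)]
                break
        return node

    root = grow(np.arange(n_total), depth=0)
    tree = PartitionTree(root=root)
    if tree.n_leaves == 1:
        warnings.warn(
            "no admissible split at the root; the partition is a single leaf "
            "and the pipeline will fall back to one global meta-model",
            stacklevel=2,
        )
    tree.validation = validate_partition(tree, train)
    return tree


# ---------------------------------------------------------------------------
# statistical validation


def validate_partition(
    tree: PartitionTree, train: TabularDataset, fdr: float = 0.05
) -> PartitionValidationReport:
    """Statistically audit a finished partition.

    Three views, matching three questions about the partition:

    * are the leaves different? — Kruskal-Wallis per feature across leaves,
      Benjamini-Hochberg adjusted;
    * does each member belong where it sits? — per-element silhouette
      against the leaf labelling, summarised per leaf;
    * is every feature informative inside every leaf? — per-leaf
      zero-variance flags.

    Violations warn rather than abort: the partition already passed its
    acceptance gates, and these diagnostics inform the user's reading of
    the final indices.
    """
    if tree.n_leaves < 2:
        return PartitionValidationReport({}, {}, {}, {}, {})

    X = train.X
    names = [c.name for c in train.feature_schemas]
    labels = tree.leaf_labels()
    leaf_ids = [lf.node_id for lf in tree.leaves]

    pvalues: dict[str, float] = {}
    for j, name in enumerate(names):
        groups = [X[labels == lid, j] for lid in leaf_ids]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvalues[name] = float(stats.kruskal(*groups).pvalue)
        except ValueError:  # all values identical in every group
            pvalues[name] = 1.0
    adjusted = dict(
        zip(pvalues, (float(p) for p in stats.false_discovery_control(list(pvalues.values()))))
    )

    sil = silhouette_samples(X, labels, metric="euclidean")
    mean_sil: dict[int, float] = {}
    pos_frac: dict[int, float] = {}
    zero_var: dict[int, list[str]] = {}
    for leaf in tree.leaves:
        s = sil[leaf.indices]
        mean_sil[leaf.node_id] = float(np.mean(s))
        pos_frac[leaf.node_id] = float(np.mean(s > 0))
        variances = X[leaf.indices].std(axis=0, ddof=0)
        zero_var[leaf.node_id] = [n for n, v in zip(names, variances) if v == 0.0]

    notes: list[str] = []
    n_nonsig = sum(1 for p in adjusted.values() if p > fdr)
    if n_nonsig > 0.5 * len(adjusted):
        notes.append(
            f"{n_nonsig}/{len(adjusted)} features show no significant "
            f"between-leaf difference at FDR {fdr}; the partition may not "
            "reflect real structure"
        )
    for lid, frac in pos_frac.items():
        if frac < 0.6:
            notes.append(
                f"leaf {lid}: only {frac:.0%} of members have positive "
                "silhouette; membership is weakly supported"
            )
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return PartitionValidationReport(
        feature_pvalues=pvalues,
        feature_pvalues_adjusted=adjusted,
        leaf_mean_silhouette=mean_sil,
        leaf_positive_silhouette_fraction=pos_frac,
        leaf_zero_variance_features=zero_var,
        warnings=notes,
    )
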