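"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(m²) loops, direct formulas, LP
feasibility — and shares no code with the package under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def pairwise_distance(u: np.ndarray, v: np.ndarray, metric: str) -> float:
    if metric == "euclidean":
        return float(np.sqrt(np.sum((u - v) ** 2)))
    if metric == "manhattan":
        return float(np.sum(np.abs(u - v)))
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        return float(1.0 - np.dot(u, v) / (nu * nv))
    raise ValueError(metric)


def brute_silhouette(X: np.ndarray, labels: np.ndarray, metric: str = "euclidean") -> float:
    """Mean silhouette via the textbook per-point formula s = (b−a)/max(a,b)."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    m = len(X)
    clusters = np.unique(labels)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            D[i, j] = pairwise_distance(X[i], X[j], metric)
    s = np.zeros(m)
    for i in range(m):
        own = labels[i]
        same = np.flatnonzero((labels == own) & (np.arange(m) != i))
        if len(same) == 0:
            s[i] = 0.0
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == other].mean() for other in clusters if other != own)
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def brute_calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Between/within dispersion ratio scaled by (m−k)/(k−1)."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    m = len(X)
    clusters = np.unique(labels)
    k = len(clusters)
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in clusters:
        Xc = X[labels == c]
        centre = Xc.mean(axis=0)
        between += len(Xc) * np.sum((centre - grand) ** 2)
        within += np.sum((Xc - centre) ** 2)
    return float((between / within) * ((m - k) / (k - 1)))


def lp_separable(X: np.ndarray, y: np.ndarray) -> bool:
    """Exact linear-separability oracle: LP feasibility of sᵢ(w·xᵢ+c) ≥ 1."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.unique(y)
    assert len(labels) == 2
    s = np.where(np.asarray(y) == labels[0], 1.0, -1.0)
    A = -(np.column_stack([X, np.ones(len(X))]) * s[:, None])
    res = linprog(
        c=np.zeros(X.shape[1] + 1),
        A_ub=A,
        b_ub=-np.ones(len(X)),
        bounds=[(None, None)] * (X.shape[1] + 1),
        method="highs",
    )
    return res.status == 0


def pooled_accuracy(per_leaf_correct: list[int], per_leaf_size: list[int]) -> float:
    return sum(per_leaf_correct) / sum(per_leaf_size)
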