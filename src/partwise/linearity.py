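"""Linearity assessment: how far do purely linear models get on this data?

Regression tasks are probed with ordinary least squares (held-out R²);
classification tasks with a battery of maximum-margin linear classifiers
plus a Ho-Kashyap separability test.  The best linear score, ``x_linear``,
is both the verdict baseline (linear vs non-linear at the user's threshold)
and the denominator of the final improvement index I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score, r2_score
from sklearn.svm import SVC, LinearSVC

from .config import RunConfig
from .preprocessing import SplitPair

__all__ = [
    "LinearityReport",
    "assess_linearity",
    "assess_linearity_regression",
    "assess_linearity_classification",
    "ho_kashyap_separability",
]


@dataclass
class LinearityReport:
    """Outcome of the linearity stage.

    ``x_linear`` is the best linear performance observed (held-out R² for
    regression, held-out accuracy for classification), clipped to [0, 1];
    the verdict is ``linear`` iff it reaches the configured threshold.
    """

    x_linear: float
    best_linear_model: str
    threshold: float
    verdict: str
    details: dict | None = None

    def to_dict(self) -> dict:
        return {
            "x_linear": self.x_linear,
            "best_linear_model": self.best_linear_model,
            "threshold": self.threshold,
            "verdict": self.verdict,
            "details": self.details,
        }


def _verdict(x_linear: float, threshold: float) -> str:
    return "linear" if x_linear >= threshold else "non_linear"


def assess_linearity_regression(split: SplitPair, config: RunConfig) -> LinearityReport:
    """Fit OLS on the training rows; score R² on the held-out validation rows.

    The fit goes through the pseudoinverse, so rank-deficient designs (e.g.
    duplicated features) degrade gracefully to the minimum-norm solution
    with a warning rather than an error.
    """
    Xtr = split.train.X
    Xval = split.validation.X
    A = np.column_stack([Xtr, np.ones(len(Xtr))])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("rank-deficient design; OLS solved by pseudoinverse", stacklevel=2)
    coef, *_ = np.linalg.lstsq(A, split.train.y.astype(np.float64), rcond=None)
    pred = np.column_stack([Xval, np.ones(len(Xval))]) @ coef
    r2 = r2_score(split.validation.y.astype(np.float64), pred)
    x_linear = float(np.clip(r2, 0.0, 1.0))
    return LinearityReport(
        x_linear=x_linear,
        best_linear_model="ordinary_least_squares",
        threshold=config.linear_threshold,
        verdict=_verdict(x_linear, config.linear_threshold),
        details={"validation_r2_raw": float(r2)},
    )


def ho_kashyap_separability(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 1000,
    lr: float = 0.9,
    tol: float = 1e-6,
) -> tuple[bool, float]:
    """Classic Ho-Kashyap test for linear separability of two classes.

    Minimises ‖Ya − b‖² over the weight vector ``a`` and the *positive*
    margin vector ``b``, alternating a least-squares update of ``a`` with a
    positive-part gradient update of ``b``.  Rows of ``Y`` are the augmented
    samples, with the second class negated, so ``Ya > 0`` everywhere means a
    separating hyperplane has been found — which is exactly the convergence
    certificate of the procedure.

    Returns
    -------
    (separable, margin_accuracy) : separable is True iff all margins became
    positive within ``max_iter``; margin_accuracy is the training accuracy
    of the final hyperplane either way.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.unique(y)
    if len(labels) != 2:
        raise ValueError(f"Ho-Kashyap needs exactly 2 classes, got {len(labels)}")
    sign = np.where(np.asarray(y) == labels[0], 1.0, -1.0)
    Y = np.column_stack([X, np.ones(len(X))]) * sign[:, None]
    Y_pinv = np.linalg.pinv(Y)
    b = np.ones(len(X))
    a = Y_pinv @ b
    separable = False
    for _ in range(max_iter):
        e = Y @ a - b
        if np.all(Y @ a > tol):
            separable = True
            break
        if np.all(e <= tol):
            break  # error has no positive part left: certified non-separable
        # b may only grow where the error is positive, keeping b > 0
        b = b + lr * (e + np.abs(e))
        a = Y_pinv @ b
    margins = Y @ a
    margin_accuracy = float(np.mean(margins > 0))
    return separable, margin_accuracy


def _hk_one_vs_rest(Xtr, ytr, Xval, yval) -> float:
    """Validation accuracy of one-vs-rest Ho-Kashyap hyperplanes."""
    classes = np.unique(ytr)
    scores = np.empty((len(Xval), len(classes)))
    for j, cls in enumerate(classes):
        y_bin = np.where(ytr == cls, 1.0, -1.0)
        Y = np.column_stack([Xtr, np.ones(len(Xtr))]) * y_bin[:, None]
        Y_pinv = np.linalg.pinv(Y)
        b = np.ones(len(Xtr))
        a = Y_pinv @ b
        for _ in range(1000):
            e = Y @ a - b
            if np.all(Y @ a > 1e-6):
                break
            b = b + 0.9 * (e + np.abs(e))
            a = Y_pinv @ b
        scores[:, j] = np.column_stack([Xval, np.ones(len(Xval))]) @ a
    pred = classes[np.argmax(scores, axis=1)]
    return float(accuracy_score(yval, pred))


def assess_linearity_classification(split: SplitPair, config: RunConfig) -> LinearityReport:
    """Best held-out accuracy over a linear maximum-margin battery.

    The battery spans linear-kernel SVMs over a small regularisation grid
    with both L1 and L2 penalties, plus the Ho-Kashyap one-vs-rest
    hyperplanes.  ``x_linear`` is the maximum validation accuracy observed.
    """
    Xtr, ytr = split.train.X, split.train.y
    Xval, yval = split.validation.X, split.validation.y
    if set(np.unique(yval)) - set(np.unique(ytr)):
        raise ValueError("validation split holds classes absent from training")

    battery: dict[str, object] = {}
    for C in (0.1, 1.0, 10.0):
        battery[f"linear_svm_l2_C{C}"] = LinearSVC(C=C, max_iter=5000)
        battery[f"linear_svm_l1_C{C}"] = LinearSVC(
            C=C, penalty="l1", dual=False, max_iter=5000
        )
    battery["svc_linear_kernel"] = SVC(kernel="linear")

    scores: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LinearSVC convergence chatter
        for name, model in battery.items():
            model.fit(Xtr, ytr)
            scores[name] = float(accuracy_score(yval, model.predict(Xval)))
    scores["ho_kashyap_ovr"] = _hk_one_vs_rest(Xtr, ytr, Xval, yval)

    best_name = max(scores, key=lambda k: (scores[k], k))
    x_linear = float(np.clip(scores[best_name], 0.0, 1.0))
    return LinearityReport(
        x_linear=x_linear,
        best_linear_model=best_name,
        threshold=config.linear_threshold,
        verdict=_verdict(x_linear, config.linear_threshold),
        details={"battery_scores": scores},
    )


def assess_linearity(split: SplitPair, config: RunConfig) -> LinearityReport:
    """Dispatch on the task: OLS R² (regression) or linear battery (classification)."""
    if config.task == "regression":
        return assess_linearity_regression(split, config)
    return assess_linearity_classification(split, config)
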