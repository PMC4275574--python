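"""Sparse (L1) and dense (L2) linear maximum-margin classifiers.

The decision function is ``f(x) = sign(w'x)`` with no bias term. The sparse
machine minimizes ``||w||_1 + C * sum_i max(1 - y_i w'x_i, 0)^2`` (squared
hinge), which drives a subset of the weights to exact zero; its support
identifies the connections that carry the discrimination. The dense
comparison machine is the standard L2-regularized hinge SVM,
``0.5 ||w||^2 + C * sum_i max(1 - y_i w'x_i, 0)``.

Both are solved by LIBLINEAR coordinate descent (via scikit-learn), which
for the L1 problem yields exact zeros; the support threshold ``eps`` only
guards against floating-point noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

__all__ = [
    "TrainedLinearModel",
    "train_l1_svm",
    "train_l2_svm",
    "predict",
    "l2_stability_support",
]

SUPPORT_EPS = 1e-8


@dataclass
class TrainedLinearModel:
    """A trained linear classifier ``f(x) = sign(w'x)``."""

    weights: np.ndarray
    penalty: str              # "l1" or "l2"
    C: float
    eps: float = SUPPORT_EPS
    meta: dict = field(default_factory=dict)

    @property
    def q(self) -> int:
        return self.weights.shape[0]

    @property
    def support(self) -> np.ndarray:
        """Indices of weights with magnitude above ``eps``."""
        return np.flatnonzero(np.abs(self.weights) > self.eps)

    @property
    def sparsity(self) -> float:
        """Fraction of nonzero weights, |support| / q."""
        return self.support.size / self.q


def _check_training_inputs(X: np.ndarray, y: np.ndarray, C: float) -> tuple:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, q) with matching labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    classes = np.unique(y)
    if not np.array_equal(classes, [-1, 1]):
        raise ValueError("labels must contain both classes, coded -1/+1")
    if C <= 0:
        raise ValueError("C must be positive")
    return X, y.astype(int)


def train_l1_svm(X, y, C: float, tol: float = 1e-6,
                 max_iter: int = 10000) -> TrainedLinearModel:
    """Minimize ``||w||_1 + C * sum_i max(1 - y_i w'x_i, 0)^2`` (no bias)."""
    X, y = _check_training_inputs(X, y, C)
    svc = LinearSVC(penalty="l1", loss="squared_hinge", dual=False, C=C,
                    fit_intercept=False, tol=tol, max_iter=max_iter,
                    random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(X, y)
    w = svc.coef_[0].copy()
    if svc.classes_[1] != 1:  # pragma: no cover - sklearn sorts classes
        w = -w
    return TrainedLinearModel(w, "l1", C, meta={"tol": tol, "max_iter": max_iter})


def train_l2_svm(X, y, C: float, tol: float = 1e-5,
                 max_iter: int = 50000) -> TrainedLinearModel:
    """Minimize ``0.5 ||w||^2 + C * sum_i max(1 - y_i w'x_i, 0)`` (no bias)."""
    X, y = _check_training_inputs(X, y, C)
    svc = LinearSVC(penalty="l2", loss="hinge", dual=True, C=C,
                    fit_intercept=False, tol=tol, max_iter=max_iter,
                    random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(X, y)
    w = svc.coef_[0].copy()
    if svc.classes_[1] != 1:  # pragma: no cover
        w = -w
    return TrainedLinearModel(w, "l2", C, meta={"tol": tol, "max_iter": max_iter})


def predict(model: TrainedLinearModel, X) -> np.ndarray:
    """Class labels ``sign(w'x)`` per row; an exact zero score maps to +1."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.q:
        raise ValueError(f"expected {model.q} features, got {X.shape[1]}")
    scores = X @ model.weights
    return np.where(scores >= 0.0, 1, -1)


def l2_stability_support(model: TrainedLinearModel,
                         trim_fraction: float = 0.01) -> np.ndarray:
    """Effective support of a dense weight vector for stability scoring.

    The smallest-magnitude weights whose cumulative absolute sum does not
    exceed ``trim_fraction`` of ``||w||_1`` are zeroed (largest such prefix in
    ascending |w| order); the surviving indices are returned. This gives the
    dense L2 machine a sparse "pattern" comparable with the L1 support.
    """
    if model.penalty != "l2":
        raise ValueError("stability trimming applies to L2 models")
    w = np.abs(model.weights)
    nz = np.flatnonzero(w > 0)
    if nz.size == 0:
        return np.array([], dtype=int)
    order = nz[np.argsort(w[nz], kind="stable")]
    budget = trim_fraction * w.sum()
    cum = np.cumsum(w[order])
    removed = order[cum <= budget]
    keep = np.setdiff1d(nz, removed)
    return keep
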