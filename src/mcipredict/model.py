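"""Linear soft-margin SVM in explicit dual form, plus confusion metrics.

The classifier is the maximum-margin hyperplane

    y(x) = sum_n w_n * t_n * k(x, x_n) + b ,    k(u, v) = u . v

with per-sample dual weights ``w_n >= 0`` (zero off the support vectors),
training labels ``t_n`` in {-1, +1} and bias ``b``.  For the linear kernel
the primal weight vector ``w = sum_n w_n t_n x_n`` is stored alongside the
dual expansion and the two are verified to agree.

The positive class (+1) is the progressive group (pMCI + AD): sensitivity is
the detection rate of subjects who progress, specificity of those who do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = ["SvmModel", "Metrics", "svm_train", "svm_decision", "svm_classify",
           "compute_metrics"]

_DUAL_PRIMAL_TOL = 1e-8


@dataclass
class SvmModel:
    dual_weights: np.ndarray  # w_n >= 0 per training sample, 0 off support
    labels: np.ndarray  # t_n in {-1, +1}
    support_vectors: np.ndarray  # retained training samples
    support_indices: np.ndarray
    bias: float
    primal_w: np.ndarray
    cost_c: float
    kernel: str = "linear"

    @property
    def n_features(self) -> int:
        return self.primal_w.shape[0]


def svm_train(X: np.ndarray, y: np.ndarray, cost_c: float = 1.0) -> SvmModel:
    """Train a linear soft-margin SVM (deterministic for fixed input)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError("X must be samples x features")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    if cost_c <= 0:
        raise ValueError("cost_c must be positive")
    clf = SVC(kernel="linear", C=cost_c, tol=1e-8)
    clf.fit(X, y)
    n = X.shape[0]
    dual = np.zeros(n)
    # sklearn's dual_coef_ holds t_n * w_n for the support vectors
    dual[clf.support_] = np.abs(clf.dual_coef_[0])
    primal_w = clf.coef_[0].astype(float)
    bias = float(clf.intercept_[0])
    expansion = (dual * y) @ X
    if not np.allclose(expansion, primal_w, atol=1e-6 * max(1.0, np.abs(primal_w).max())):
        raise AssertionError("dual expansion does not reproduce the primal weights")
    return SvmModel(
        dual_weights=dual,
        labels=y.copy(),
        support_vectors=X[clf.support_].copy(),
        support_indices=clf.support_.copy(),
        bias=bias,
        primal_w=primal_w,
        cost_c=cost_c,
    )


def svm_decision(model: SvmModel, x: np.ndarray) -> np.ndarray | float:
    """Signed distance-like decision value ``w . x + b``.

    Accepts a single feature vector or a samples-by-features matrix; the
    primal evaluation agrees with the dual expansion to 1e-8.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    d = X @ model.primal_w + model.bias
    return float(d[0]) if single else d


def svm_dual_decision(model: SvmModel, x: np.ndarray) -> float:
    """Decision value via the kernel expansion; used as a cross-check."""
    x = np.asarray(x, dtype=float)
    w = model.dual_weights[model.support_indices]
    t = model.labels[model.support_indices]
    return float(np.sum(w * t * (model.support_vectors @ x)) + model.bias)


def svm_classify(model: SvmModel, x: np.ndarray) -> np.ndarray | int:
    """Sign of the decision value; a tie at exactly 0 maps to +1."""
    d = svm_decision(model, x)
    if np.isscalar(d):
        return 1 if d >= 0 else -1
    return np.where(np.asarray(d) >= 0, 1, -1)


@dataclass
class Metrics:
    """Confusion counts and derived rates; NaN flags an undefined ratio
    (empty positive or negative stratum) rather than silently reporting 0."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.tp + self.tn + self.fp + self.fn
        self.accuracy = (self.tp + self.tn) / total if total else float("nan")
        pos, neg = self.tp + self.fn, self.tn + self.fp
        self.sensitivity = self.tp / pos if pos else float("nan")
        self.specificity = self.tn / neg if neg else float("nan")


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return Metrics(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )
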