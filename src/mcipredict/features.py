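"""Feature extraction and ranking fitted on training data only.

Two feature-extraction routes are provided for the voxel stream:

* PCA followed by Fisher-discriminant-ratio (FDR) ranking of the
  coefficients, and
* PLS (one-block partial least squares against the binary label), where the
  number of retained components plays the role of the feature count.

Neuropsychological scores bypass PCA: they are z-score normalized with
training statistics and FDR-ranked directly.  The FDR used throughout is the
class-separability index

    FDR = (mu_A - mu_B)^2 / (var_A + var_B)

with sample variances (n-1 denominator); it is *not* the false-discovery
rate.  Every fit in this module is a function of its training inputs alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassStats",
    "RankingResult",
    "PcaModel",
    "PlsModel",
    "ZScoreStats",
    "fdr_rank",
    "pca_fit",
    "pca_transform",
    "pls_fit",
    "pls_transform",
    "zscore_fit",
    "zscore_apply",
    "assemble_features",
]


@dataclass
class ClassStats:
    """Per-feature class means and sample variances (A = label -1, B = +1)."""

    mu_a: np.ndarray
    mu_b: np.ndarray
    var_a: np.ndarray
    var_b: np.ndarray


@dataclass
class RankingResult:
    """Features sorted by FDR, ties broken by ascending original index."""

    order: np.ndarray
    fdr_values: np.ndarray  # aligned with ``order`` (non-increasing)
    stats: ClassStats

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def _check_two_classes(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    neg, pos = y == -1, y == +1
    if not (neg.any() and pos.any()):
        raise ValueError("both classes (-1 and +1) must be present")
    if neg.sum() < 2 or pos.sum() < 2:
        raise ValueError("need at least 2 samples per class")
    return neg, pos


def fdr_rank(X: np.ndarray, y: np.ndarray) -> RankingResult:
    """Rank feature columns by the Fisher discriminant ratio.

    A zero denominator with a nonzero numerator maps to ``+inf`` (a
    zero-variance, perfectly separated feature ranks first); 0/0 maps to 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D (samples x features)")
    neg, pos = _check_two_classes(y)
    mu_a, mu_b = X[neg].mean(axis=0), X[pos].mean(axis=0)
    var_a = X[neg].var(axis=0, ddof=1)
    var_b = X[pos].var(axis=0, ddof=1)
    num = (mu_a - mu_b) ** 2
    den = var_a + var_b
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                       np.where(num > 0, np.inf, 0.0))
    order = np.argsort(-fdr, kind="stable")  # stable: ties keep ascending index
    return RankingResult(
        order=order,
        fdr_values=fdr[order],
        stats=ClassStats(mu_a=mu_a, mu_b=mu_b, var_a=var_a, var_b=var_b),
    )


# --------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    """Training-mean-centered PCA with a deterministic sign convention.

    ``training_scores`` caches the coefficients of the training samples (a
    by-product of the fit); ``pca_transform`` on the training data returns
    the same values.
    """

    mean: np.ndarray
    loadings: np.ndarray  # (n_features, n_components), orthonormal columns
    explained_variance: np.ndarray  # non-increasing, ddof=1 convention
    training_scores: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca_fit(X_train: np.ndarray, n_components: int | None = None) -> PcaModel:
    """Fit PCA on training samples; at most ``n_samples - 1`` components.

    For wide matrices (features >> samples) the eigen-decomposition is done
    on the n x n Gram matrix of the centered data (the dual route), which is
    algebraically identical to the SVD of the data matrix.  The sign of each
    component is fixed so that its largest-magnitude loading entry is
    positive (eigenvector signs are otherwise arbitrary).
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("PCA needs a 2D matrix with >= 2 training samples")
    n_samples, n_features = X_train.shape
    bound = min(n_samples - 1, n_features)
    k = bound if n_components is None else min(int(n_components), bound)
    mean = X_train.mean(axis=0)
    Xc = X_train - mean
    if n_features > 2 * n_samples:
        gram = Xc @ Xc.T
        evals, evecs = np.linalg.eigh(gram)  # ascending
        evals, evecs = evals[::-1][:k], evecs[:, ::-1][:, :k]
        svals = np.sqrt(np.clip(evals, 0.0, None))
        safe = np.where(svals > 0, svals, 1.0)
        loadings = (Xc.T @ evecs) / safe
        scores = evecs * svals
        explained = np.clip(evals, 0.0, None) / (n_samples - 1)
    else:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = Vt[:k].T.copy()
        scores = U[:, :k] * s[:k]
        explained = (s[:k] ** 2) / (n_samples - 1)
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings *= signs
    scores = scores * signs
    return PcaModel(
        mean=mean,
        loadings=loadings,
        explained_variance=explained,
        training_scores=scores,
    )


def pca_transform(X: np.ndarray, model: PcaModel) -> np.ndarray:
    """Project samples onto the PCA subspace: ``(X - mean) @ loadings``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.mean.shape[0]})"
        )
    return (X - model.mean) @ model.loadings


# --------------------------------------------------------------------------
# PLS


@dataclass
class PlsModel:
    """One-block PLS against a centered binary label, fitted by deflation.

    ``weights`` holds the unit-norm projection directions computed on the
    successively deflated training matrix; ``rotations`` maps *undeflated*
    centered data to the component scores (so the model applies directly to
    held-out samples).
    """

    x_mean: np.ndarray
    weights: np.ndarray  # (n_features, n_components), unit columns
    x_loadings: np.ndarray  # regression loadings used in the deflation
    rotations: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


def pls_fit(X_train: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """Fit PLS components maximizing covariance with the label vector.

    The first direction is proportional to ``X_c.T @ y_c``; each subsequent
    direction is computed on the residual of X after deflating the fitted
    component.
    """
    X_train = np.asarray(X_train, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_two_classes(y)
    n_samples, n_features = X_train.shape
    if not (1 <= n_components <= min(n_samples - 1, n_features)):
        raise ValueError(
            f"n_components={n_components} out of range "
            f"[1, {min(n_samples - 1, n_features)}]"
        )
    x_mean = X_train.mean(axis=0)
    Xc = X_train - x_mean
    yc = y - y.mean()

    W = np.zeros((n_features, n_components))
    P = np.zeros((n_features, n_components))
    Xd = Xc.copy()
    for a in range(n_components):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            # No remaining covariance with the label; fall back to an
            # arbitrary unit direction so downstream shapes stay valid.
            w = np.zeros(n_features)
            w[a % n_features] = 1.0
        else:
            w = w / norm
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt if tt > 0 else np.zeros(n_features)
        Xd = Xd - np.outer(t, p)
        W[:, a], P[:, a] = w, p
    rotations = W @ np.linalg.pinv(P.T @ W)
    return PlsModel(x_mean=x_mean, weights=W, x_loadings=P, rotations=rotations)


def pls_transform(X: np.ndarray, model: PlsModel, k: int | None = None) -> np.ndarray:
    """Scores of (possibly held-out) samples on the first ``k`` components."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.shape[0]:
        raise ValueError("feature dimension does not match PLS model")
    k = model.n_components if k is None else int(k)
    if not (1 <= k <= model.n_components):
        raise ValueError(f"k={k} outside [1, {model.n_components}]")
    if k == model.n_components:
        R = model.rotations
    else:
        W, P = model.weights[:, :k], model.x_loadings[:, :k]
        R = W @ np.linalg.pinv(P.T @ W)
    return (X - model.x_mean) @ R


# --------------------------------------------------------------------------
# score normalization


@dataclass
class ZScoreStats:
    mean: np.ndarray
    sd: np.ndarray  # sample sd (ddof=1); zero marks a degenerate column


def zscore_fit(X_train: np.ndarray) -> ZScoreStats:
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("z-scoring needs >= 2 training samples")
    return ZScoreStats(
        mean=X_train.mean(axis=0), sd=X_train.std(axis=0, ddof=1)
    )


def zscore_apply(X: np.ndarray, stats: ZScoreStats) -> np.ndarray:
    """Apply training z-score statistics; constant columns map to all zeros."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != stats.mean.shape[0]:
        raise ValueError(
            f"score width {X.shape[1]} does not match fitted stats "
            f"({stats.mean.shape[0]})"
        )
    degenerate = stats.sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant score column(s); outputs set to 0",
            stacklevel=2,
        )
    sd = np.where(degenerate, 1.0, stats.sd)
    out = (X - stats.mean) / sd
    out[:, degenerate] = 0.0
    return out


# --------------------------------------------------------------------------
# assembly


def assemble_features(
    mri_coeffs: np.ndarray | None,
    score_matrix: np.ndarray | None,
    mri_ranking: RankingResult | None,
    score_ranking: RankingResult | None,
    k_mri: int,
    k_np: int,
    score_names: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Concatenate top-ranked MRI coefficients and top-ranked scores.

    Returns the feature matrix and one provenance label per column
    (``mri:<source column>`` or ``np:<score name>``).
    """
    if k_mri < 0 or k_np < 0 or k_mri + k_np < 1:
        raise ValueError("need k_mri >= 0, k_np >= 0 and k_mri + k_np >= 1")
    blocks, labels = [], []
    if k_mri > 0:
        if mri_coeffs is None or mri_ranking is None:
            raise ValueError("k_mri > 0 but no MRI coefficients/ranking given")
        if k_mri > mri_coeffs.shape[1]:
            raise ValueError(f"k_mri={k_mri} exceeds {mri_coeffs.shape[1]} columns")
        cols = mri_ranking.top(k_mri)
        blocks.append(mri_coeffs[:, cols])
        labels.extend(f"mri:{int(c)}" for c in cols)
    if k_np > 0:
        if score_matrix is None or score_ranking is None:
            raise ValueError("k_np > 0 but no score matrix/ranking given")
        if k_np > score_matrix.shape[1]:
            raise ValueError(f"k_np={k_np} exceeds {score_matrix.shape[1]} scores")
        cols = score_ranking.top(k_np)
        blocks.append(score_matrix[:, cols])
        if score_names is None:
            labels.extend(f"np:score_{int(c):03d}" for c in cols)
        else:
            labels.extend(f"np:{score_names[int(c)]}" for c in cols)
    return np.hstack(blocks), labels
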