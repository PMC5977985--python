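"""Predictor-interpretation artifacts: voxel importance maps and
neuropsychological predictor frequencies.

For a linear SVM trained on PCA coefficients the weight vector lives in
coefficient space; restricting it to the MRI columns and back-projecting
through the PCA loadings gives a weight per voxel.  Because backward-model
weights are not directly interpretable as class-related signal, the forward
"activation pattern" A = Cov(X_train) @ w is computed in the trained feature
space before back-projection.  Per-fold voxel maps are averaged in absolute
value (so sign flips between folds do not cancel informative voxels),
min-max normalized to [0, 1], and reported with a display threshold
(default 35%).

Neuropsychological predictors are summarized by how often each score was
selected across the outer CV rounds; scores above a frequency cutoff
(default 5%) are flagged as best predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import PcaModel
from .model import SvmModel
from .selection import FoldResult, PerformanceSummary

__all__ = [
    "ImportanceMap",
    "PredictorFrequencyTable",
    "split_feature_weights",
    "primal_voxel_weights",
    "activation_pattern",
    "aggregate_maps",
    "predictor_frequency",
    "fold_voxel_importance",
    "importance_map_from_run",
    "predictor_frequency_from_run",
]


@dataclass
class ImportanceMap:
    """Normalized voxel-importance grid in [0, 1] with a display threshold."""

    values: np.ndarray  # 3D, min 0 / max 1 unless degenerate (all zero)
    threshold: float = 0.35
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")

    def thresholded(self) -> np.ndarray:
        """Copy with sub-threshold voxels zeroed (the display variant)."""
        out = self.values.copy()
        out[out < self.threshold] = 0.0
        return out

    def support(self) -> np.ndarray:
        return self.values >= self.threshold


@dataclass
class PredictorFrequencyTable:
    """Selection frequency per score, descending; rows above the cutoff are
    flagged as best predictors."""

    table: pd.DataFrame  # columns: name, frequency, flagged
    cutoff: float = 0.05
    n_rounds: int = 0


def split_feature_weights(
    w: np.ndarray, feature_labels: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a feature-space vector into (mri part, component indices, np part)."""
    if len(feature_labels) != w.shape[0]:
        raise ValueError("provenance labels do not match the weight vector")
    mri_pos = [i for i, lab in enumerate(feature_labels) if lab.startswith("mri:")]
    np_pos = [i for i, lab in enumerate(feature_labels) if lab.startswith("np:")]
    if len(mri_pos) + len(np_pos) != len(feature_labels):
        bad = [l for l in feature_labels if not l.startswith(("mri:", "np:"))]
        raise ValueError(f"unrecognized provenance labels: {bad[:3]}")
    comp = np.array([int(feature_labels[i].split(":", 1)[1]) for i in mri_pos],
                    dtype=int)
    return w[mri_pos], comp, w[np_pos]


def primal_voxel_weights(
    model: SvmModel, pca: PcaModel, feature_labels: list[str]
) -> np.ndarray:
    """Back-project the MRI part of the primal weight vector to voxel space.

    Equivalent to summing the training samples weighted by ``w_n t_n`` on a
    voxel basis (the dual expansion), restricted to the retained components.
    """
    w_mri, comps, _ = split_feature_weights(model.primal_w, feature_labels)
    if w_mri.size == 0:
        return np.zeros(pca.loadings.shape[0])
    return pca.loadings[:, comps] @ w_mri


def activation_pattern(X_train: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Forward-model pattern A = Cov(X_train) @ w in the trained feature space."""
    X_train = np.asarray(X_train, dtype=float)
    w = np.asarray(w, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("need >= 2 training samples")
    if X_train.shape[1] != w.shape[0]:
        raise ValueError(
            f"weight length {w.shape[0]} does not match {X_train.shape[1]} features"
        )
    Xc = X_train - X_train.mean(axis=0)
    # Cov(X) @ w without materializing the feature-space covariance
    return Xc.T @ (Xc @ w) / (X_train.shape[0] - 1)


def aggregate_maps(
    per_fold_maps: list[np.ndarray],
    grid_shape: tuple[int, int, int],
    threshold: float = 0.35,
    provenance: dict | None = None,
) -> ImportanceMap:
    """Average |map| over folds and min-max normalize to [0, 1].

    A constant mean map (no dynamic range) yields an all-zero map with a
    warning instead of dividing by zero.
    """
    if not per_fold_maps:
        raise ValueError("need at least one fold map")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    stacked = np.stack([np.abs(np.asarray(m, dtype=float).reshape(-1))
                        for m in per_fold_maps])
    mean = stacked.mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi - lo <= 0:
        warnings.warn("constant importance map; returning all zeros",
                      stacklevel=2)
        values = np.zeros(grid_shape)
    else:
        values = ((mean - lo) / (hi - lo)).reshape(grid_shape)
    return ImportanceMap(values=values, threshold=threshold,
                         provenance=provenance)


def predictor_frequency(
    selected_labels_per_round: list[list[str] | set],
    cutoff: float = 0.05,
    all_names: list[str] | None = None,
) -> PredictorFrequencyTable:
    """Selection frequency of each neuropsychological score across rounds.

    frequency = (#rounds whose selected set contains the score) / (#rounds);
    sorted descending, ties by name.  Only ``np:`` labels are counted.
    """
    if not selected_labels_per_round:
        raise ValueError("need at least one round")
    n_rounds = len(selected_labels_per_round)
    counts: dict[str, int] = {}
    if all_names is not None:
        counts = {name: 0 for name in all_names}
    for labels in selected_labels_per_round:
        names = {
            lab.split(":", 1)[1]
            for lab in labels
            if isinstance(lab, str) and lab.startswith("np:")
        }
        for name in names:
            counts[name] = counts.get(name, 0) + 1
    rows = [
        {"name": name, "frequency": c / n_rounds, "flagged": c / n_rounds > cutoff}
        for name, c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["name", "frequency", "flagged"])
    df = df.sort_values(
        ["frequency", "name"], ascending=[False, True]
    ).reset_index(drop=True)
    return PredictorFrequencyTable(table=df, cutoff=cutoff, n_rounds=n_rounds)


# --------------------------------------------------------------------------
# run-level convenience (consumes FoldResult artifacts)


def fold_voxel_importance(fold: FoldResult) -> np.ndarray:
    """Haufe-corrected voxel importance for one outer fold.

    The activation pattern is computed in the assembled feature space the
    SVM was trained in, then its MRI block is back-projected through the
    fold's PCA loadings.  Requires the run to have kept its models.
    """
    if fold.artifacts is None:
        raise ValueError("fold has no retained artifacts (keep_models=False?)")
    art = fold.artifacts
    if art["pca"] is None:
        raise ValueError("voxel maps require the pca_fdr extractor")
    A = activation_pattern(art["X_train"], art["svm"].primal_w)
    a_mri, comps, _ = split_feature_weights(A, art["feature_labels"])
    if a_mri.size == 0:
        return np.zeros(art["pca"].loadings.shape[0])
    return art["pca"].loadings[:, comps] @ a_mri


def importance_map_from_run(
    summary: PerformanceSummary,
    grid_shape: tuple[int, int, int],
    threshold: float = 0.35,
) -> ImportanceMap:
    """Fold-averaged, normalized importance map for a completed nested-CV run."""
    per_fold = [fold_voxel_importance(f) for f in summary.fold_results]
    return aggregate_maps(
        per_fold, grid_shape, threshold=threshold,
        provenance={
            "timepoint": summary.timepoint,
            "extractor": summary.extractor,
            "n_folds": len(summary.fold_results),
        },
    )


def predictor_frequency_from_run(
    summary: PerformanceSummary, cutoff: float = 0.05,
    all_names: list[str] | None = None,
) -> PredictorFrequencyTable:
    return predictor_frequency(
        [f.selected_feature_labels for f in summary.fold_results],
        cutoff=cutoff, all_names=all_names,
    )
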