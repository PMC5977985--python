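"""Fivefold nested cross-validation with wrapper feature selection.

The outer loop estimates generalization performance; the inner loop, run on
the outer training portion only, chooses the preprocessing and feature
configuration (tissue channel, smoothing FWHM, number of MRI features,
number of neuropsychological scores) that maximizes validation accuracy.
With 200 subjects and 5x5 folds each round uses 128 subjects to train, 32 to
validate and 40 to test.

No quantity fitted on one side of a split ever touches the other side:
PCA/PLS models, FDR rankings and z-score statistics are fitted inside each
inner training partition, and the winning configuration is refitted on the
full outer-training portion before the single evaluation on the untouched
test fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import inf

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import features as feat
from .model import Metrics, compute_metrics, svm_classify, svm_train
from .synthetic import CohortBundle

logger = logging.getLogger(__name__)

__all__ = [
    "GridPoint",
    "NestedSplit",
    "FoldResult",
    "PerformanceSummary",
    "FWHM_GRID",
    "default_grid",
    "nested_partition",
    "inner_select",
    "run_nested_cv",
]

#: Smoothing grid searched by the wrapper: no smoothing or FWHM 2-12 mm.
FWHM_GRID = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)

_CHANNEL_ORDER = {"whole_brain": 0, "GM": 1, "WM": 2}

MODALITIES = ("mri_only", "mri_plus_np", "np_only")


@dataclass(frozen=True)
class GridPoint:
    """One wrapper candidate.  ``k_mri=None`` means all available components."""

    channel: str
    fwhm_mm: float
    k_mri: int | None
    k_np: int
    extractor: str = "pca_fdr"

    def __post_init__(self) -> None:
        if self.extractor not in ("pca_fdr", "pls"):
            raise ValueError(f"unknown extractor {self.extractor!r}")
        k_mri = self.k_mri if self.k_mri is not None else 1
        if k_mri < 0 or self.k_np < 0 or k_mri + self.k_np < 1:
            raise ValueError("need k_mri + k_np >= 1 with non-negative counts")

    def sort_key(self) -> tuple:
        """Tie-break order: smaller k_mri, then k_np, then fwhm, then WB<GM<WM."""
        k = inf if self.k_mri is None else self.k_mri
        return (k, self.k_np, self.fwhm_mm, _CHANNEL_ORDER.get(self.channel, 99))


def default_grid(
    extractor: str = "pca_fdr",
    channels: tuple[str, ...] = ("whole_brain", "GM", "WM"),
    fwhm_values: tuple[float, ...] = FWHM_GRID,
    k_mri_values: tuple = (1, 2, 5, 10, 20, 50, None),
    k_np_values: tuple[int, ...] = (0, 1, 2, 5, 10, 20, 64),
) -> list[GridPoint]:
    """The wrapper search grid; ``None`` in ``k_mri_values`` means "all"."""
    grid = []
    for ch in channels:
        for fwhm in fwhm_values:
            for k_mri in k_mri_values:
                for k_np in k_np_values:
                    if (k_mri or 0) + k_np < 1 and k_mri is not None:
                        continue
                    grid.append(GridPoint(ch, float(fwhm), k_mri, int(k_np),
                                          extractor))
    return grid


@dataclass
class NestedSplit:
    outer_fold_id: int
    outer_test_ids: np.ndarray
    trainval_ids: np.ndarray
    inner_folds: list[tuple[np.ndarray, np.ndarray]]  # (train_ids, validation_ids)


def nested_partition(
    n: int, k_outer: int, k_inner: int, y: np.ndarray, seed: int
) -> list[NestedSplit]:
    """Stratified nested folds; deterministic given the seed.

    Outer test sets partition the sample; within each outer round the inner
    folds partition the outer-training portion.  Class proportions are
    preserved per fold to within one sample.
    """
    y = np.asarray(y)
    if not (2 <= k_outer <= n) or k_inner < 2:
        raise ValueError("need n >= k_outer >= 2 and k_inner >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k_outer:
        raise ValueError(
            f"smallest class ({counts.min()}) too small for {k_outer} "
            "stratified outer folds"
        )
    idx = np.arange(n)
    outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed % 2**31)
    splits = []
    for fold_id, (trainval, test) in enumerate(outer.split(idx, y)):
        inner_seed = (seed * 100003 + 7919 * fold_id + 1) % 2**31
        inner = StratifiedKFold(
            n_splits=k_inner, shuffle=True, random_state=inner_seed
        )
        inner_folds = [
            (trainval[tr], trainval[va])
            for tr, va in inner.split(trainval, y[trainval])
        ]
        splits.append(
            NestedSplit(
                outer_fold_id=fold_id,
                outer_test_ids=test,
                trainval_ids=trainval,
                inner_folds=inner_folds,
            )
        )
    return splits


@dataclass
class FoldResult:
    outer_fold_id: int
    chosen: GridPoint
    inner_validation_accuracy: float
    metrics: Metrics
    selected_feature_labels: list[str]
    artifacts: dict | None = None  # models/matrices retained for map building


@dataclass
class PerformanceSummary:
    timepoint: str
    modality: str
    extractor: str
    fold_results: list[FoldResult]
    metric_means: dict[str, float] = field(init=False)
    metric_sds: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.metric_means, self.metric_sds = {}, {}
        for m in ("accuracy", "sensitivity", "specificity"):
            vals = np.array([getattr(f.metrics, m) for f in self.fold_results])
            self.metric_means[m] = float(np.mean(vals))
            self.metric_sds[m] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def fold_values(self, metric: str = "accuracy") -> np.ndarray:
        return np.array([getattr(f.metrics, metric) for f in self.fold_results])


# --------------------------------------------------------------------------
# feature-building context


class FeatureContext:
    """Caches per-(channel, FWHM) flattened voxel matrices for one cohort.

    Smoothing is a per-subject preprocessing step (it never mixes subjects),
    so the smoothed feature matrices are shared across folds; everything that
    is *fitted* (PCA/PLS, rankings, z-scores) stays fold-local.
    """

    def __init__(
        self,
        bundle: CohortBundle,
        timepoint: str,
        mask: np.ndarray | None = None,
        labels_override: np.ndarray | None = None,
    ):
        cfg = bundle.config
        if timepoint not in cfg.timepoints:
            raise ValueError(
                f"timepoint {timepoint!r} not in cohort {cfg.timepoints}"
            )
        self.bundle = bundle
        self.timepoint = timepoint
        self.y = (
            np.asarray(labels_override, dtype=int)
            if labels_override is not None
            else bundle.binary_labels()
        )
        if self.y.shape[0] != bundle.n_subjects:
            raise ValueError("labels_override length mismatch")
        self.scores = bundle.score_matrix(timepoint)
        self.score_names = list(bundle.truth["score_names"])
        self.grid_shape = cfg.grid_shape
        self.voxel_size_mm = cfg.voxel_size_mm
        if mask is not None and tuple(mask.shape) != tuple(cfg.grid_shape):
            raise ValueError("mask incongruent with cohort grid")
        self.mask_flat = (
            np.asarray(mask, dtype=bool).reshape(-1) if mask is not None else None
        )
        self._raw: dict[str, np.ndarray] = {}
        self._flat: dict[tuple[str, float], np.ndarray] = {}

    def mri(self, channel: str, fwhm_mm: float) -> np.ndarray:
        """(n_subjects, n_voxels) matrix for one channel/smoothing setting."""
        key = (channel, float(fwhm_mm))
        if key not in self._flat:
            if channel not in self._raw:
                if channel not in self.bundle.config.channels:
                    raise ValueError(f"channel {channel!r} not in cohort")
                self._raw[channel] = self.bundle.volume_array(
                    self.timepoint, channel
                )
            data = self._raw[channel]
            if fwhm_mm > 0:
                from .volumes import fwhm_to_sigma

                sigma = [0.0] + [
                    fwhm_to_sigma(fwhm_mm, s) for s in self.voxel_size_mm
                ]
                from scipy import ndimage

                data = ndimage.gaussian_filter(data, sigma=sigma, mode="reflect")
            flat = data.reshape(data.shape[0], -1)
            if self.mask_flat is not None:
                flat = flat[:, self.mask_flat]
            self._flat[key] = np.ascontiguousarray(flat)
        return self._flat[key]


# --------------------------------------------------------------------------
# stream fitting (one (channel, fwhm, extractor) combination on one split)


@dataclass
class _FittedStreams:
    """Fold-local fitted feature machinery for one preprocessing combination."""

    extractor: str
    pca: feat.PcaModel | None
    pls: feat.PlsModel | None
    mri_coeff_train: np.ndarray | None
    mri_ranking: feat.RankingResult | None
    zstats: feat.ZScoreStats | None
    z_train: np.ndarray | None
    score_ranking: feat.RankingResult | None
    n_mri_available: int

    def mri_block(self, coeffs: np.ndarray, k: int) -> tuple[np.ndarray, list[str]]:
        if self.extractor == "pca_fdr":
            cols = self.mri_ranking.top(k)
            return coeffs[:, cols], [f"mri:{int(c)}" for c in cols]
        return coeffs[:, :k], [f"mri:{c}" for c in range(k)]


def _fit_streams(
    ctx: FeatureContext,
    train_idx: np.ndarray,
    channel: str | None,
    fwhm: float,
    extractor: str,
    need_mri: bool,
    need_np: bool,
    max_k_mri: int,
) -> tuple[_FittedStreams, np.ndarray | None]:
    """Fit all training-side feature machinery; returns (streams, X_mri_full)."""
    y_train = ctx.y[train_idx]
    pca = pls = mri_ranking = None
    coeff_train = None
    X_full = None
    n_avail = 0
    if need_mri:
        X_full = ctx.mri(channel, fwhm)
        X_train = X_full[train_idx]
        if extractor == "pca_fdr":
            pca = feat.pca_fit(X_train)
            coeff_train = pca.training_scores
            mri_ranking = feat.fdr_rank(coeff_train, y_train)
            n_avail = pca.n_components
        else:
            n_avail = min(max_k_mri, X_train.shape[0] - 1, X_train.shape[1])
            pls = feat.pls_fit(X_train, y_train, n_components=n_avail)
            coeff_train = feat.pls_transform(X_train, pls)
    zstats = z_train = score_ranking = None
    if need_np:
        zstats = feat.zscore_fit(ctx.scores[train_idx])
        z_train = feat.zscore_apply(ctx.scores[train_idx], zstats)
        score_ranking = feat.fdr_rank(z_train, y_train)
    return (
        _FittedStreams(
            extractor=extractor,
            pca=pca,
            pls=pls,
            mri_coeff_train=coeff_train,
            mri_ranking=mri_ranking,
            zstats=zstats,
            z_train=z_train,
            score_ranking=score_ranking,
            n_mri_available=n_avail,
        ),
        X_full,
    )


def _transform_mri(streams: _FittedStreams, X: np.ndarray) -> np.ndarray:
    if streams.extractor == "pca_fdr":
        return feat.pca_transform(X, streams.pca)
    return feat.pls_transform(X, streams.pls)


def _assemble(
    streams: _FittedStreams,
    ctx: FeatureContext,
    coeffs: np.ndarray | None,
    idx: np.ndarray,
    k_mri: int,
    k_np: int,
) -> tuple[np.ndarray, list[str]]:
    blocks, labels = [], []
    if k_mri > 0:
        block, lab = streams.mri_block(coeffs, k_mri)
        blocks.append(block)
        labels.extend(lab)
    if k_np > 0:
        z = feat.zscore_apply(ctx.scores[idx], streams.zstats)
        cols = streams.score_ranking.top(k_np)
        blocks.append(z[:, cols])
        labels.extend(f"np:{ctx.score_names[int(c)]}" for c in cols)
    return np.hstack(blocks), labels


def _effective_k_mri(gp: GridPoint, n_available: int) -> int:
    if gp.k_mri is None:
        return n_available
    return min(gp.k_mri, n_available)


def inner_select(
    ctx: FeatureContext,
    split: NestedSplit,
    grid: list[GridPoint],
    cost_c: float = 1.0,
) -> tuple[GridPoint, float]:
    """Average validation accuracy over the inner folds for every grid point
    and return the maximizer (ties: smaller k_mri, k_np, fwhm, WB<GM<WM)."""
    if not grid:
        raise ValueError("wrapper grid must not be empty")
    grid_sorted = sorted(grid, key=GridPoint.sort_key)
    max_k_mri = max(
        (gp.k_mri for gp in grid if gp.k_mri is not None), default=0
    )
    if any(gp.k_mri is None for gp in grid):
        max_k_mri = max(max_k_mri, len(split.inner_folds[0][0]) - 1)

    acc_sums: dict[GridPoint, float] = {gp: 0.0 for gp in grid_sorted}
    for train_idx, val_idx in split.inner_folds:
        combos: dict[tuple, _FittedStreams] = {}
        combo_val: dict[tuple, np.ndarray | None] = {}
        eff_cache: dict[tuple, float] = {}
        for gp in grid_sorted:
            need_mri = gp.k_mri is None or gp.k_mri > 0
            key = (gp.channel if need_mri else None,
                   gp.fwhm_mm if need_mri else 0.0,
                   gp.extractor)
            if key not in combos:
                streams, X_full = _fit_streams(
                    ctx, train_idx, key[0], key[1], gp.extractor,
                    need_mri=need_mri, need_np=True, max_k_mri=max_k_mri,
                )
                combos[key] = streams
                combo_val[key] = (
                    _transform_mri(streams, X_full[val_idx])
                    if need_mri else None
                )
            streams = combos[key]
            k_mri = _effective_k_mri(gp, streams.n_mri_available) if need_mri else 0
            k_np = min(gp.k_np, ctx.scores.shape[1])
            if k_mri + k_np < 1:
                continue
            eff_key = key + (k_mri, k_np)
            if eff_key not in eff_cache:
                Xtr, _ = _assemble(
                    streams, ctx,
                    streams.mri_coeff_train if k_mri else None,
                    train_idx, k_mri, k_np,
                )
                Xva, _ = _assemble(
                    streams, ctx, combo_val[key] if k_mri else None,
                    val_idx, k_mri, k_np,
                )
                svm = svm_train(Xtr, ctx.y[train_idx], cost_c=cost_c)
                pred = svm_classify(svm, Xva)
                eff_cache[eff_key] = float(np.mean(pred == ctx.y[val_idx]))
            acc_sums[gp] += eff_cache[eff_key]

    n_folds = len(split.inner_folds)
    best_gp, best_acc = None, -1.0
    for gp in grid_sorted:
        acc = acc_sums[gp] / n_folds
        if acc > best_acc:
            best_gp, best_acc = gp, acc
    return best_gp, best_acc


def _restrict_grid(grid: list[GridPoint], modality: str) -> list[GridPoint]:
    if modality == "mri_plus_np":
        return list(grid)
    seen, out = set(), []
    for gp in grid:
        if modality == "mri_only":
            if gp.k_mri is None or gp.k_mri >= 1:
                new = GridPoint(gp.channel, gp.fwhm_mm, gp.k_mri, 0, gp.extractor)
            else:
                continue
        elif modality == "np_only":
            if gp.k_np < 1:
                continue
            new = GridPoint(gp.channel, 0.0, 0, gp.k_np, gp.extractor)
        else:
            raise ValueError(f"unknown modality {modality!r}")
        if new not in seen:
            seen.add(new)
            out.append(new)
    return out


def run_nested_cv(
    bundle: CohortBundle,
    timepoint: str,
    modality: str = "mri_plus_np",
    extractor: str = "pca_fdr",
    grid: list[GridPoint] | None = None,
    seed: int = 0,
    cost_c: float = 1.0,
    k_outer: int = 5,
    k_inner: int = 5,
    mask: np.ndarray | None = None,
    labels_override: np.ndarray | None = None,
    keep_models: bool = False,
) -> PerformanceSummary:
    """Full nested-CV run for one (timepoint, modality, extractor) cell.

    For each outer round the wrapper selects its configuration on the inner
    folds, the winning configuration is refitted on the outer-training
    portion (train + validation), and the refitted model is evaluated once on
    the outer test fold.  The summary reports fold mean +/- sd per metric.
    """
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    if extractor not in ("pca_fdr", "pls"):
        raise ValueError(f"unknown extractor {extractor!r}")
    ctx = FeatureContext(bundle, timepoint, mask=mask,
                         labels_override=labels_override)
    if grid is None:
        grid = default_grid(extractor=extractor,
                            channels=bundle.config.channels)
    grid = _restrict_grid(
        [gp for gp in grid if gp.extractor == extractor], modality
    )
    if not grid:
        raise ValueError("empty wrapper grid after modality restriction")

    splits = nested_partition(ctx.y.shape[0], k_outer, k_inner, ctx.y, seed)
    max_k_mri = max((gp.k_mri for gp in grid if gp.k_mri is not None), default=0)
    fold_results = []
    for split in splits:
        chosen, inner_acc = inner_select(ctx, split, grid, cost_c=cost_c)
        tv = split.trainval_ids
        need_mri = chosen.k_mri is None or chosen.k_mri > 0
        mk = len(tv) - 1 if chosen.k_mri is None else chosen.k_mri
        streams, X_full = _fit_streams(
            ctx, tv, chosen.channel if need_mri else None,
            chosen.fwhm_mm if need_mri else 0.0, extractor,
            need_mri=need_mri, need_np=chosen.k_np > 0, max_k_mri=mk,
        )
        k_mri = _effective_k_mri(chosen, streams.n_mri_available) if need_mri else 0
        k_np = min(chosen.k_np, ctx.scores.shape[1])
        Xtr, labels = _assemble(
            streams, ctx, streams.mri_coeff_train if k_mri else None,
            tv, k_mri, k_np,
        )
        svm = svm_train(Xtr, ctx.y[tv], cost_c=cost_c)
        test = split.outer_test_ids
        coeff_test = _transform_mri(streams, X_full[test]) if k_mri else None
        Xte, _ = _assemble(streams, ctx, coeff_test, test, k_mri, k_np)
        pred = svm_classify(svm, Xte)
        metrics = compute_metrics(ctx.y[test], pred)
        logger.info(
            "fold %d: chose %s (inner acc %.3f) -> test acc %.3f",
            split.outer_fold_id, chosen, inner_acc, metrics.accuracy,
        )
        artifacts = None
        if keep_models:
            artifacts = {
                "svm": svm,
                "pca": streams.pca,
                "pls": streams.pls,
                "X_train": Xtr,
                "feature_labels": labels,
                "k_mri": k_mri,
                "k_np": k_np,
            }
        fold_results.append(
            FoldResult(
                outer_fold_id=split.outer_fold_id,
                chosen=chosen,
                inner_validation_accuracy=inner_acc,
                metrics=metrics,
                selected_feature_labels=labels,
                artifacts=artifacts,
            )
        )
    return PerformanceSummary(
        timepoint=timepoint, modality=modality, extractor=extractor,
        fold_results=fold_results,
    )
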