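"""Desk-scale study definitions exercising the pipeline end-to-end.

Each function here runs one self-contained synthetic experiment -- cohort
generation, nested-CV classification, significance testing or map recovery
-- at sizes chosen for single-CPU runtimes, and returns plain dictionaries
of the measured quantities.  The analysis drivers, the acceptance checks and
the test suite all call these, so every reported number is recomputed from
scratch.

Study design notes
------------------
* The *default* cohort uses the generator defaults (100 subjects per class,
  four time points, 64 scores with 8 informative).
* The *MRI-dominant* cohort plants a strong atrophy surrogate (1.5-3
  noise-sd) for accuracy and importance-map recovery.
* The *score-dominant* cohort plants a weak MRI effect but a strong score
  effect (d = 2.2), so the wrapper must select neuropsychological scores and
  their selection frequency is a meaningful recovery readout.  (With a
  saturating MRI effect every candidate ties at accuracy 1 and the
  tie-break prefers the smallest feature set, which never includes scores.)
* The wrapper grid used by the studies is a reduced version of the full
  default grid (3 channels x FWHM {0, 4, 8} mm x small feature counts) to
  keep runtimes at the desk scale.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .features import fdr_rank, pca_fit
from .maps import importance_map_from_run, predictor_frequency_from_run
from .model import svm_train
from .selection import (
    GridPoint,
    default_grid,
    nested_partition,
    run_nested_cv,
)
from .stats import permutation_test
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "study_grid",
    "partition_sizes_study",
    "pca_bound_study",
    "fdr_oracle_study",
    "svm_analytic_study",
    "null_calibration_study",
    "pvalue_uniformity_study",
    "signal_recovery_study",
    "modality_contrast_study",
]


def study_grid(extractor: str = "pca_fdr") -> list[GridPoint]:
    """Reduced wrapper grid for desk-scale runs."""
    return default_grid(
        extractor=extractor,
        fwhm_values=(0.0, 4.0, 8.0),
        k_mri_values=(1, 2, 5, 10),
        k_np_values=(0, 2, 5, 10),
    )


def mri_dominant_config(seed: int) -> CohortConfig:
    return CohortConfig(
        effect_delta_by_timepoint={"m24": 1.5, "m18": 2.0, "m12": 2.5, "t0": 3.0},
        score_effect_d=0.8,
        seed=seed,
    )


def score_dominant_config(seed: int) -> CohortConfig:
    return CohortConfig(
        effect_delta_by_timepoint={"m24": 0.1, "m18": 0.15, "m12": 0.2, "t0": 0.25},
        score_effect_d=2.2,
        seed=seed,
    )


def null_config(seed: int, **overrides) -> CohortConfig:
    kwargs = dict(
        effect_delta_by_timepoint={tp: 0.0 for tp in ("m24", "m18", "m12", "t0")},
        n_informative_scores=0,
        score_effect_d=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def tiny_null_config(seed: int) -> CohortConfig:
    """A minimal scores-only null cohort for replicate permutation studies.

    Sized so the fold-averaged accuracy has a reasonably fine grain (32 test
    predictions per run): with a coarse-grained statistic the >=-fraction
    p-value is noticeably conservative under ties.
    """
    return CohortConfig(
        n_per_class=16,
        grid_shape=(6, 6, 6),
        timepoints=("t0",),
        channels=("GM",),
        effect_delta_by_timepoint={"t0": 0.0},
        base_smooth_fwhm_mm=0.0,
        n_scores=8,
        n_informative_scores=0,
        score_effect_d=0.0,
        seed=seed,
    )


# --------------------------------------------------------------------------
# structural worked examples


def partition_sizes_study(seed: int = 0, n: int = 200) -> dict:
    """Train/validation/test sizes of every 5x5 nested-CV round."""
    y = np.array([-1] * (n // 2) + [1] * (n - n // 2))
    splits = nested_partition(n, 5, 5, y, seed)
    train_sizes = sorted(
        {len(tr) for s in splits for tr, _ in s.inner_folds}
    )
    val_sizes = sorted({len(va) for s in splits for _, va in s.inner_folds})
    test_sizes = sorted({len(s.outer_test_ids) for s in splits})
    return {
        "train_sizes": train_sizes,
        "validation_sizes": val_sizes,
        "test_sizes": test_sizes,
        "n": n,
    }


def pca_bound_study(seed: int = 0, n_samples: int = 200,
                    n_features: int = 400) -> dict:
    """Number of PCA components retained from a full-rank training matrix."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, n_features))
    model = pca_fit(X)
    nonzero = int(np.sum(model.explained_variance > 1e-10))
    return {"n_components": model.n_components, "n_nonzero_variance": nonzero,
            "n": n_samples}


def _fdr_brute_force(X: np.ndarray, y: np.ndarray):
    """Independent per-feature evaluation of the printed FDR formula."""
    values = []
    for j in range(X.shape[1]):
        a = [X[i, j] for i in range(X.shape[0]) if y[i] == -1]
        b = [X[i, j] for i in range(X.shape[0]) if y[i] == +1]
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        va = sum((v - ma) ** 2 for v in a) / (len(a) - 1)
        vb = sum((v - mb) ** 2 for v in b) / (len(b) - 1)
        num, den = (ma - mb) ** 2, va + vb
        if den > 0:
            values.append(num / den)
        else:
            values.append(float("inf") if num > 0 else 0.0)
    order = sorted(range(X.shape[1]), key=lambda j: (-values[j], j))
    return values, order


def fdr_oracle_study(seed: int = 0, n_instances: int = 100) -> dict:
    """Agreement rate between fdr_rank and brute-force evaluation."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        X = rng.normal(size=(30, 10))
        y = np.array([-1] * 15 + [1] * 15)
        result = fdr_rank(X, y)
        values, order = _fdr_brute_force(X, y)
        ok = np.allclose(
            result.fdr_values, [values[j] for j in order], rtol=1e-10
        ) and list(result.order) == order
        agree += int(ok)
    return {"agreement_rate": agree / n_instances, "n": n_instances}


def svm_analytic_study() -> dict:
    """Two-point max-margin problem with the closed-form solution w=1, b=-1."""
    X = np.array([[0.0], [2.0]])
    y = np.array([-1, 1])
    model = svm_train(X, y, cost_c=1e6)
    return {"w": float(model.primal_w[0]), "b": float(model.bias), "n": 2}


# --------------------------------------------------------------------------
# pipeline-level studies


def null_calibration_study(seed: int = 0, timepoint: str = "m24") -> dict:
    """Nested-CV accuracy on the default cohort with shuffled labels.

    Under the shuffle the features carry no label information, so accuracy
    should sit within two binomial standard errors of 0.5.
    """
    bundle = generate_cohort(CohortConfig(seed=seed))
    rng = np.random.default_rng(seed + 1)
    shuffled = rng.permutation(bundle.binary_labels())
    summary = run_nested_cv(
        bundle, timepoint, modality="mri_plus_np", extractor="pca_fdr",
        grid=study_grid(), seed=seed, labels_override=shuffled,
    )
    n = bundle.n_subjects
    return {
        "accuracy": summary.metric_means["accuracy"],
        "two_se_band": 2 * float(np.sqrt(0.25 / n)),
        "n": n,
    }


def pvalue_uniformity_study(
    seed: int = 0, n_repeats: int = 200, n_iter: int = 39
) -> dict:
    """Distribution of permutation p-values on null cohorts.

    Each repeat draws a fresh scores-only null cohort, runs a small 3x3
    nested-CV permutation test, and records the accuracy p-value.  Under
    exchangeability the p-values are (discretely) uniform; reported are the
    Kolmogorov-Smirnov p against U(0,1) and the fraction with p <= 0.05.
    """
    grid = [GridPoint("GM", 0.0, 0, 4, "pca_fdr")]
    pvals = []
    for r in range(n_repeats):
        bundle = generate_cohort(tiny_null_config(seed * n_repeats + r + 1))
        res = permutation_test(
            bundle, "t0", modality="np_only", grid=grid,
            n_iter=n_iter, seed=seed * n_repeats + r + 1,
            k_outer=4, k_inner=4,
        )
        pvals.append(res.p_values["accuracy"])
    pvals = np.asarray(pvals)
    ks = sps.kstest(pvals, "uniform")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "type_i_rate": float(np.mean(pvals <= 0.05)),
        "n": n_repeats,
        "n_iter": n_iter,
    }


def signal_recovery_study(
    seed: int = 0, n_seeds: int = 5, timepoint: str = "m24"
) -> dict:
    """Accuracy, importance-map and predictor recovery on planted cohorts.

    Per seed: (a) an MRI-dominant cohort is classified and its fold-averaged
    importance map compared with the planted mask (fraction of top-decile
    voxels inside it); (b) a score-dominant cohort is classified with both
    streams and the selection frequencies of the planted scores compared to
    those of the noise scores.  Medians over seeds are reported.
    """
    accuracies, overlaps, freq_ok, freq_margins = [], [], [], []
    for s in range(n_seeds):
        child = seed * 1000 + s

        bundle = generate_cohort(mri_dominant_config(child))
        summary = run_nested_cv(
            bundle, timepoint, modality="mri_plus_np", extractor="pca_fdr",
            grid=study_grid(), seed=child, keep_models=True,
        )
        accuracies.append(summary.metric_means["accuracy"])
        imap = importance_map_from_run(summary, bundle.config.grid_shape)
        values = imap.values.reshape(-1)
        n_top = max(1, values.size // 10)
        top = np.argsort(-values)[:n_top]
        mask_flat = bundle.truth["effect_mask"].reshape(-1)
        overlaps.append(float(mask_flat[top].mean()))

        bundle2 = generate_cohort(score_dominant_config(child))
        summary2 = run_nested_cv(
            bundle2, timepoint, modality="mri_plus_np", extractor="pca_fdr",
            grid=study_grid(), seed=child,
        )
        table = predictor_frequency_from_run(summary2).table
        names = bundle2.truth["score_names"]
        informative = {names[i] for i in bundle2.truth["informative_scores"]}
        freq = dict(zip(table.name, table.frequency))
        inf_freqs = [freq.get(n, 0.0) for n in informative]
        noise_freqs = [f for n, f in freq.items() if n not in informative]
        max_noise = max(noise_freqs, default=0.0)
        freq_margins.append(min(inf_freqs) - max_noise)
        top_row_informative = (
            not table.empty
            and table.frequency.iloc[0] == 1.0
            and table.name.iloc[0] in informative
        )
        freq_ok.append(
            float(top_row_informative and min(inf_freqs) >= max_noise)
        )
    return {
        "accuracy_median": float(np.median(accuracies)),
        "accuracies": accuracies,
        "map_overlap_median": float(np.median(overlaps)),
        "map_overlaps": overlaps,
        "score_recovery_median": float(np.median(freq_ok)),
        "score_frequency_margins": freq_margins,
        "n": n_seeds,
    }


def modality_contrast_study(seed: int = 0, timepoint: str = "m24") -> dict:
    """Accuracy of MRI-only vs. MRI+neuropsychology on the same cohort.

    Mirrors the direction of the multimodal-vs-unimodal contrast: adding
    informative scores should not reduce accuracy by more than fold noise.
    """
    bundle = generate_cohort(CohortConfig(seed=seed))
    mri = run_nested_cv(
        bundle, timepoint, modality="mri_only", extractor="pca_fdr",
        grid=study_grid(), seed=seed,
    )
    both = run_nested_cv(
        bundle, timepoint, modality="mri_plus_np", extractor="pca_fdr",
        grid=study_grid(), seed=seed,
    )
    k = len(mri.fold_results)
    fold_se = float(mri.metric_sds["accuracy"] / np.sqrt(k))
    return {
        "mri_only_accuracy": mri.metric_means["accuracy"],
        "combined_accuracy": both.metric_means["accuracy"],
        "gain": both.metric_means["accuracy"] - mri.metric_means["accuracy"],
        "fold_se": fold_se,
        "n": bundle.n_subjects,
    }
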