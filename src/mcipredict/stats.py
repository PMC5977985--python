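"""Permutation significance testing and performance comparisons.

The permutation test reruns the *complete* nested-CV pipeline -- including
the inner wrapper selection -- under random permutations of the binary
labels, so the null distribution carries the same selection-induced optimism
as the observed statistic.  The p-value is the plain fraction of null values
greater than or equal to the observed one (resolution 1/n_iter; it can be
exactly 0).  A smoothed (r+1)/(n+1) estimator is available behind a flag.

Cross-configuration comparisons use the two-sided paired t-test on matched
fold metrics and one-way fixed-effects ANOVA across time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .selection import GridPoint, run_nested_cv
from .synthetic import CohortBundle

__all__ = [
    "PermutationResult",
    "ComparisonResult",
    "permutation_pvalue",
    "permutation_test",
    "paired_comparison",
    "anova_timepoints",
]

METRICS = ("accuracy", "sensitivity", "specificity")


def permutation_pvalue(
    null_values, observed: float, smoothed: bool = False
) -> float:
    """Fraction of null values >= observed; optionally the (r+1)/(n+1) form."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 1:
        raise ValueError("need at least one permutation iteration")
    r = int(np.sum(null_values >= observed))
    n = null_values.size
    return (r + 1) / (n + 1) if smoothed else r / n


@dataclass
class PermutationResult:
    observed: dict[str, float]
    null_distributions: dict[str, np.ndarray]
    p_values: dict[str, float]
    n_iter: int
    seed: int


def permutation_test(
    bundle: CohortBundle,
    timepoint: str,
    modality: str = "mri_plus_np",
    extractor: str = "pca_fdr",
    grid: list[GridPoint] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    cv_seed: int | None = None,
    smoothed: bool = False,
    **cv_kwargs,
) -> PermutationResult:
    """Label-permutation null for the nested-CV performance metrics.

    Permutation i uses a child generator derived from ``seed`` via a counter,
    so iterations are reproducible (and independently re-runnable).  The
    fold partition seed (``cv_seed``, default ``seed``) is shared between the
    observed run and every permuted rerun.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    cv_seed = seed if cv_seed is None else cv_seed
    observed_summary = run_nested_cv(
        bundle, timepoint, modality=modality, extractor=extractor,
        grid=grid, seed=cv_seed, **cv_kwargs,
    )
    observed = {m: observed_summary.metric_means[m] for m in METRICS}
    y = bundle.binary_labels()
    null: dict[str, list[float]] = {m: [] for m in METRICS}
    for i in range(n_iter):
        rng = np.random.default_rng([seed % 2**31, i])
        permuted = rng.permutation(y)
        summary = run_nested_cv(
            bundle, timepoint, modality=modality, extractor=extractor,
            grid=grid, seed=cv_seed, labels_override=permuted, **cv_kwargs,
        )
        for m in METRICS:
            null[m].append(summary.metric_means[m])
    null_arr = {m: np.asarray(v) for m, v in null.items()}
    p_values = {
        m: permutation_pvalue(null_arr[m], observed[m], smoothed=smoothed)
        for m in METRICS
    }
    return PermutationResult(
        observed=observed, null_distributions=null_arr, p_values=p_values,
        n_iter=n_iter, seed=seed,
    )


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    test: str
    dof: tuple | float
    pairwise: list[dict] | None = None


def paired_comparison(
    metric_per_fold_a, metric_per_fold_b
) -> ComparisonResult:
    """Two-sided paired t-test on matched fold metrics.

    All-zero differences (identical performance in every fold) give
    statistic 0 and p = 1 rather than the NaN of the raw t formula.
    """
    a = np.asarray(metric_per_fold_a, dtype=float)
    b = np.asarray(metric_per_fold_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D fold-metric vectors")
    if a.size < 2:
        raise ValueError("need at least 2 matched folds")
    d = a - b
    if np.allclose(d, 0):
        return ComparisonResult(0.0, 1.0, "paired_t", float(a.size - 1))
    t, p = sps.ttest_rel(a, b)
    return ComparisonResult(float(t), float(p), "paired_t", float(a.size - 1))


def anova_timepoints(
    metric_per_fold_by_timepoint: dict[str, np.ndarray] | list,
    pairwise: bool = False,
) -> ComparisonResult:
    """One-way fixed-effects ANOVA of a fold metric across time points.

    With ``pairwise=True`` all-pairs two-sample t-tests are attached,
    unadjusted for multiplicity (labelled as such).
    """
    if isinstance(metric_per_fold_by_timepoint, dict):
        names = list(metric_per_fold_by_timepoint)
        groups = [np.asarray(metric_per_fold_by_timepoint[n], dtype=float)
                  for n in names]
    else:
        groups = [np.asarray(g, dtype=float) for g in metric_per_fold_by_timepoint]
        names = [f"group{i}" for i in range(len(groups))]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    dof = (k - 1, n_total - k)
    if all(np.allclose(g, groups[0][0]) for g in groups):
        result = ComparisonResult(0.0, 1.0, "one_way_anova", dof)
    else:
        f, p = sps.f_oneway(*groups)
        result = ComparisonResult(float(f), float(p), "one_way_anova", dof)
    if pairwise:
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                if np.allclose(groups[i], groups[j]) and (
                    groups[i].std() == groups[j].std() == 0
                ):
                    t, p = 0.0, 1.0  # identical constant groups
                else:
                    t, p = sps.ttest_ind(groups[i], groups[j])
                rows.append(
                    {"a": names[i], "b": names[j], "t": float(t),
                     "p_unadjusted": float(p)}
                )
        result.pairwise = rows
    return result
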