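#!/usr/bin/env python
"""Significance analyses: permutation test of the full pipeline and
fold-level comparisons across time points, modalities and extractors.

The permutation test reruns the complete nested-CV pipeline (inner
selection included) under label permutations on a reduced cohort, at
n_iter = 99 for desk-scale runtime (the procedure defaults to 1000).
Comparisons reuse the matched fold metrics written by 02_nested_cv_tables.

Writes ``results/significance.json``.
"""

import json
from pathlib import Path

from mcipredict.selection import GridPoint
from mcipredict.stats import anova_timepoints, paired_comparison, permutation_test
from mcipredict.synthetic import CohortConfig, generate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def reduced_cohort():
    return generate_cohort(
        CohortConfig(
            n_per_class=20, grid_shape=(10, 12, 10), n_scores=16,
            n_informative_scores=4, seed=SEED,
        )
    )


def main() -> None:
    out: dict = {}

    grid = [GridPoint("GM", fw, k, kn)
            for fw in (0.0, 4.0) for k in (1, 5) for kn in (0, 4)]
    perm = permutation_test(
        reduced_cohort(), "m24", modality="mri_plus_np", grid=grid,
        n_iter=99, seed=SEED,
    )
    out["permutation"] = {
        "observed": perm.observed, "p_values": perm.p_values,
        "n_iter": perm.n_iter,
    }
    print("permutation test (m24, MRI+NP, n_iter=99):")
    for m, p in perm.p_values.items():
        print(f"  {m}: observed {perm.observed[m]:.3f}, p = {p:.3f}")

    folds = json.load(open(RESULTS / "fold_metrics.json"))

    out["anova_across_timepoints"] = {}
    for key_prefix in ("pca_fdr|mri_only", "pca_fdr|mri_plus_np",
                       "pls|mri_only", "pls|mri_plus_np"):
        groups = {
            tp: folds[f"{key_prefix}|{tp}"]["accuracy"]
            for tp in ("m24", "m18", "m12", "t0")
        }
        r = anova_timepoints(groups, pairwise=True)
        out["anova_across_timepoints"][key_prefix] = {
            "F": r.statistic, "p": r.p_value, "dof": list(r.dof),
            "pairwise_unadjusted": r.pairwise,
        }
        print(f"ANOVA accuracy across timepoints [{key_prefix}]: "
              f"F = {r.statistic:.3f}, p = {r.p_value:.3f}")

    out["mri_vs_multimodal"] = {}
    for tp in ("m24", "m18", "m12", "t0"):
        r = paired_comparison(
            folds[f"pca_fdr|mri_plus_np|{tp}"]["accuracy"],
            folds[f"pca_fdr|mri_only|{tp}"]["accuracy"],
        )
        out["mri_vs_multimodal"][tp] = {"t": r.statistic, "p": r.p_value}
        print(f"paired t (MRI+NP vs MRI alone, {tp}): "
              f"t = {r.statistic:.3f}, p = {r.p_value:.3f}")

    out["pca_vs_pls"] = {}
    for modality in ("mri_only", "mri_plus_np"):
        for tp in ("m24", "t0"):
            r = paired_comparison(
                folds[f"pca_fdr|{modality}|{tp}"]["accuracy"],
                folds[f"pls|{modality}|{tp}"]["accuracy"],
            )
            out["pca_vs_pls"][f"{modality}|{tp}"] = {
                "t": r.statistic, "p": r.p_value
            }

    with open(RESULTS / "significance.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print("-> significance.json written.")


if __name__ == "__main__":
    main()
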