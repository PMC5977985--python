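#!/usr/bin/env python
"""Generate the default synthetic cohort and characterize its planted effects.

Writes ``results/cohort_summary.csv`` with, per time point, the standardized
group difference of the mean gray-matter intensity inside the planted mask
(the atrophy surrogate the classifier should exploit) and the mean absolute
group gap of the informative vs. noise score columns.  Also exports a
4-subject miniature cohort under ``scratch/cohort_demo/`` to demonstrate the
NIfTI/CSV on-disk layout.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mcipredict.synthetic import CohortConfig, generate_cohort, write_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    bundle = generate_cohort(CohortConfig(seed=0))
    cfg = bundle.config
    y = bundle.binary_labels()
    mask = bundle.truth["effect_mask"]
    info = bundle.truth["informative_scores"]
    noise = np.setdiff1d(np.arange(cfg.n_scores), info)

    rows = []
    for tp in cfg.timepoints:
        masked = np.array(
            [s.volumes[(tp, "GM")].intensities[mask].mean()
             for s in bundle.subjects]
        )
        pooled = np.sqrt(
            (masked[y == -1].var(ddof=1) + masked[y == 1].var(ddof=1)) / 2
        )
        X = bundle.score_matrix(tp)
        gaps = np.abs(X[y == 1].mean(axis=0) - X[y == -1].mean(axis=0))
        rows.append(
            {
                "timepoint": tp,
                "planted_delta": cfg.effect_delta_by_timepoint[tp],
                "masked_mean_cohen_d":
                    (masked[y == -1].mean() - masked[y == 1].mean()) / pooled,
                "informative_score_gap": gaps[info].mean(),
                "noise_score_gap": gaps[noise].mean(),
            }
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(f"cohort: {bundle.n_subjects} subjects, grid {cfg.grid_shape}, "
          f"{int(mask.sum())} mask voxels, {len(info)} informative scores")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print("-> the masked-mean effect size grows toward stable diagnosis, "
          "as planted.")

    demo = generate_cohort(
        CohortConfig(n_per_class=2, grid_shape=(8, 9, 8), seed=0)
    )
    manifest = write_cohort(demo, SCRATCH / "cohort_demo")
    print(f"demo cohort written -> {manifest}")


if __name__ == "__main__":
    main()
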