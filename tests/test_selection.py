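"""Nested-CV partitioning, wrapper selection and end-to-end runs."""

import copy

import numpy as np
import pytest

from mcipredict.selection import (
    FeatureContext,
    GridPoint,
    default_grid,
    inner_select,
    nested_partition,
    run_nested_cv,
)
from mcipredict.synthetic import CohortConfig, generate_cohort

TINY_GRID = [
    GridPoint("GM", 0.0, 1, 0),
    GridPoint("GM", 0.0, 2, 0),
    GridPoint("GM", 0.0, 2, 3),
    GridPoint("GM", 2.0, 2, 3),
]


class TestPartition:
    def test_canonical_sizes_at_200(self):
        y = np.array([-1] * 100 + [1] * 100)
        splits = nested_partition(200, 5, 5, y, seed=0)
        assert len(splits) == 5
        for s in splits:
            assert len(s.outer_test_ids) == 40
            assert len(s.trainval_ids) == 160
            for tr, va in s.inner_folds:
                assert len(tr) == 128 and len(va) == 32

    def test_sizes_at_50(self):
        y = np.array([-1] * 25 + [1] * 25)
        splits = nested_partition(50, 5, 5, y, seed=1)
        for s in splits:
            assert len(s.outer_test_ids) == 10
            for tr, va in s.inner_folds:
                assert len(tr) == 32 and len(va) == 8

    def test_outer_tests_partition_sample(self):
        y = np.array([-1] * 30 + [1] * 30)
        splits = nested_partition(60, 5, 5, y, seed=3)
        all_test = np.concatenate([s.outer_test_ids for s in splits])
        assert sorted(all_test) == list(range(60))

    def test_train_val_test_disjoint(self):
        y = np.array([-1] * 30 + [1] * 30)
        for s in nested_partition(60, 5, 5, y, seed=3):
            test = set(s.outer_test_ids)
            for tr, va in s.inner_folds:
                assert not (set(tr) & set(va))
                assert not (set(tr) | set(va)) & test

    def test_stratification_within_one(self):
        y = np.array([-1] * 40 + [1] * 40)
        for s in nested_partition(80, 5, 5, y, seed=9):
            pos = np.sum(y[s.outer_test_ids] == 1)
            assert abs(pos - len(s.outer_test_ids) / 2) <= 1

    def test_deterministic_given_seed(self):
        y = np.array([-1] * 20 + [1] * 20)
        a = nested_partition(40, 5, 5, y, seed=4)
        b = nested_partition(40, 5, 5, y, seed=4)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.outer_test_ids, sb.outer_test_ids)
            for (ta, va), (tb, vb) in zip(sa.inner_folds, sb.inner_folds):
                np.testing.assert_array_equal(ta, tb)
                np.testing.assert_array_equal(va, vb)

    def test_small_class_rejected(self):
        y = np.array([-1] * 3 + [1] * 37)
        with pytest.raises(ValueError, match="class"):
            nested_partition(40, 5, 5, y, seed=0)


class TestInnerSelect:
    def test_singleton_grid_returned(self, tiny_null_cohort):
        ctx = FeatureContext(tiny_null_cohort, "t0")
        split = nested_partition(24, 4, 3, ctx.y, seed=0)[0]
        gp = GridPoint("GM", 0.0, 2, 0)
        chosen, acc = inner_select(ctx, split, [gp])
        assert chosen == gp and 0.0 <= acc <= 1.0

    def test_informative_channel_beats_noise_channel(self, tiny_cohort):
        """The planted effect lives in GM; the wrapper must find it."""
        ctx = FeatureContext(tiny_cohort, "t0")
        split = nested_partition(24, 4, 3, ctx.y, seed=0)[0]
        grid = [GridPoint("whole_brain", 0.0, 2, 0), GridPoint("GM", 0.0, 2, 0)]
        chosen, acc = inner_select(ctx, split, grid)
        assert chosen.channel == "GM"
        # confirm by recomputing both inner accuracies through the API
        _, acc_wb = inner_select(ctx, split, [grid[0]])
        _, acc_gm = inner_select(ctx, split, [grid[1]])
        assert acc_gm > acc_wb and acc == acc_gm

    def test_equal_accuracy_tie_breaks_to_smaller_k(self, tiny_cohort):
        """k_mri=50 and k_mri=None clamp to the same effective model, so
        their accuracies tie exactly and the smaller sort key wins."""
        ctx = FeatureContext(tiny_cohort, "t0")
        split = nested_partition(24, 4, 3, ctx.y, seed=0)[0]
        grid = [GridPoint("GM", 0.0, None, 0), GridPoint("GM", 0.0, 50, 0)]
        chosen, _ = inner_select(ctx, split, grid)
        assert chosen.k_mri == 50

    def test_empty_grid_rejected(self, tiny_cohort):
        ctx = FeatureContext(tiny_cohort, "t0")
        split = nested_partition(24, 4, 3, ctx.y, seed=0)[0]
        with pytest.raises(ValueError, match="grid"):
            inner_select(ctx, split, [])


class TestRunNestedCv:
    def test_separable_cohort_high_accuracy(self, tiny_cohort):
        s = run_nested_cv(tiny_cohort, "t0", grid=TINY_GRID, seed=0,
                          k_outer=4, k_inner=3)
        assert s.metric_means["accuracy"] >= 0.95

    def test_mean_is_average_of_folds(self, tiny_cohort):
        s = run_nested_cv(tiny_cohort, "t0", grid=TINY_GRID, seed=0,
                          k_outer=4, k_inner=3)
        assert s.metric_means["accuracy"] == pytest.approx(
            float(np.mean(s.fold_values("accuracy")))
        )

    def test_shuffled_labels_near_chance(self, tiny_cohort):
        rng = np.random.default_rng(5)
        shuffled = rng.permutation(tiny_cohort.binary_labels())
        s = run_nested_cv(tiny_cohort, "t0", grid=TINY_GRID, seed=0,
                          k_outer=4, k_inner=3, labels_override=shuffled)
        band = 2 * np.sqrt(0.25 / 24)
        assert abs(s.metric_means["accuracy"] - 0.5) <= band

    def test_deterministic(self, tiny_cohort):
        a = run_nested_cv(tiny_cohort, "t0", grid=TINY_GRID, seed=2,
                          k_outer=4, k_inner=3)
        b = run_nested_cv(tiny_cohort, "t0", grid=TINY_GRID, seed=2,
                          k_outer=4, k_inner=3)
        assert [f.chosen for f in a.fold_results] == [
            f.chosen for f in b.fold_results
        ]
        assert a.metric_means == b.metric_means

    def test_mri_only_never_selects_scores(self, tiny_cohort):
        s = run_nested_cv(tiny_cohort, "t0", modality="mri_only",
                          grid=TINY_GRID, seed=0, k_outer=4, k_inner=3)
        for f in s.fold_results:
            assert f.chosen.k_np == 0
            assert all(lab.startswith("mri:") for lab in
                       f.selected_feature_labels)

    def test_missing_timepoint_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="timepoint"):
            run_nested_cv(tiny_cohort, "m12", grid=TINY_GRID, seed=0)

    def test_leakage_guard_outer_test_perturbation(self, tiny_cohort):
        """Corrupting outer-test subjects must not change the wrapper's
        choice for that fold (selection sees only the inner 4/5)."""
        grid = TINY_GRID
        base = run_nested_cv(tiny_cohort, "t0", grid=grid, seed=1,
                             k_outer=4, k_inner=3)
        splits = nested_partition(24, 4, 3, tiny_cohort.binary_labels(),
                                  seed=1)
        corrupted = copy.deepcopy(tiny_cohort)
        rng = np.random.default_rng(99)
        for idx in splits[0].outer_test_ids:
            subj = corrupted.subjects[idx]
            for key in subj.volumes:
                subj.volumes[key].intensities += rng.normal(
                    0, 5, size=subj.volumes[key].intensities.shape
                )
            for tp in subj.scores:
                subj.scores[tp] = subj.scores[tp] + rng.normal(0, 5, 10)
        after = run_nested_cv(corrupted, "t0", grid=grid, seed=1,
                              k_outer=4, k_inner=3)
        assert after.fold_results[0].chosen == base.fold_results[0].chosen

    def test_accuracy_monotone_in_effect_size(self):
        """Mean accuracy at planted effects {0, small, large} is
        non-decreasing up to one binomial SE of slack."""
        accs = []
        for delta in (0.0, 0.6, 3.0):
            cfg = CohortConfig(
                n_per_class=12, grid_shape=(6, 6, 6), timepoints=("t0",),
                channels=("GM",), effect_delta_by_timepoint={"t0": delta},
                base_smooth_fwhm_mm=0.0, n_scores=4, n_informative_scores=0,
                score_effect_d=0.0, seed=21,
            )
            bundle = generate_cohort(cfg)
            s = run_nested_cv(bundle, "t0", modality="mri_only",
                              grid=[GridPoint("GM", 0.0, 2, 0)], seed=0,
                              k_outer=4, k_inner=3)
            accs.append(s.metric_means["accuracy"])
        slack = np.sqrt(0.25 / 24)
        assert accs[1] >= accs[0] - slack
        assert accs[2] >= accs[1] - slack


def test_default_grid_structure():
    grid = default_grid()
    assert all(gp.extractor == "pca_fdr" for gp in grid)
    assert {gp.channel for gp in grid} == {"whole_brain", "GM", "WM"}
    assert 0.0 in {gp.fwhm_mm for gp in grid}  # "no smoothing" is searched
    assert not any(
        (gp.k_mri == 0 and gp.k_np == 0) for gp in grid
    )
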