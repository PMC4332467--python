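"""Balanced folds, cross-validation, metrics, grid search, and the symmetry score."""

import numpy as np
import pytest

from gaitsym import (
    CohortConfig,
    ConfusionCounts,
    GaitDataset,
    GaitPattern,
    KernelSpec,
    cross_validate,
    grid_search,
    make_balanced_folds,
    metrics_from_confusion,
    simulate_patterns,
    subject_mean_patterns,
    symmetry_score,
)
from gaitsym.errors import FoldError, GaitSymError
from gaitsym.evaluate import best_per_feature_mode, render_comparison_table, score_from_accuracy


def handmade_dataset(n_subjects, rng, n_per_side=1):
    patterns = []
    for i in range(n_subjects):
        for side in ("left", "right"):
            for t in range(n_per_side):
                patterns.append(
                    GaitPattern(f"S{i:02d}", side, f"T{t}", rng.uniform(0, 120, 101))
                )
    return GaitDataset(patterns)


class TestMetrics:
    def test_hand_arithmetic(self):
        m = metrics_from_confusion(ConfusionCounts(tp=9, fp=2, tn=8, fn=1))
        assert (m.accuracy, m.sensitivity, m.specificity) == (0.85, 0.90, 0.80)

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_undefined_sensitivity_flagged(self):
        m = metrics_from_confusion(ConfusionCounts(tp=0, fp=3, tn=5, fn=0))
        assert not m.sensitivity_defined
        assert np.isnan(m.sensitivity)
        assert m.specificity_defined

    def test_empty_table_rejected(self):
        with pytest.raises(GaitSymError):
            metrics_from_confusion(ConfusionCounts(0, 0, 0, 0))

    def test_counts_validate(self):
        with pytest.raises(GaitSymError):
            ConfusionCounts(-1, 0, 0, 0)


class TestFolds:
    def test_sixty_per_side_six_folds(self, rng):
        ds = handmade_dataset(60, rng)
        folds = make_balanced_folds(ds, k=6, seed=0)
        _, y, _ = ds.matrix()
        for f in range(6):
            assert np.sum((folds == f) & (y == 1)) == 10
            assert np.sum((folds == f) & (y == -1)) == 10

    def test_subject_pairs_stay_together(self, rng):
        ds = handmade_dataset(12, rng)
        folds = make_balanced_folds(ds, k=6, seed=3)
        _, _, subjects = ds.matrix()
        for s in set(subjects):
            assert len(set(folds[subjects == s])) == 1

    def test_leave_pair_out(self, rng):
        ds = handmade_dataset(4, rng)
        folds = make_balanced_folds(ds, k=4, seed=1)
        assert sorted(np.bincount(folds)) == [2, 2, 2, 2]

    def test_deterministic_in_seed(self, rng):
        ds = handmade_dataset(60, rng)
        a = make_balanced_folds(ds, k=6, seed=7)
        b = make_balanced_folds(ds, k=6, seed=7)
        c = make_balanced_folds(ds, k=6, seed=8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_non_divisible_subject_count_rejected(self, rng):
        with pytest.raises(FoldError, match="divisible"):
            make_balanced_folds(handmade_dataset(10, rng), k=6, seed=0)

    def test_unbalanced_classes_rejected(self, rng):
        ds = handmade_dataset(6, rng)
        broken = GaitDataset(ds.patterns[1:])
        with pytest.raises(FoldError):
            make_balanced_folds(broken, k=3, seed=0)

    def test_pattern_level_mode(self, rng):
        ds = handmade_dataset(6, rng, n_per_side=2)
        folds = make_balanced_folds(ds, k=4, pairing="pattern_level", seed=0)
        _, y, _ = ds.matrix()
        for f in range(4):
            assert np.sum((folds == f) & (y == 1)) == 3
            assert np.sum((folds == f) & (y == -1)) == 3


class TestCrossValidate:
    @pytest.mark.parametrize("mode", ["all_101", "six_params", "pca"])
    @pytest.mark.parametrize("kernel", [KernelSpec("linear"), KernelSpec("poly", degree=2), KernelSpec("rbf", sigma=5.0)])
    def test_separable_asymmetry_is_perfect(self, asymmetric_cohort, mode, kernel):
        dataset, _ = asymmetric_cohort
        res = cross_validate(dataset, feature_mode=mode, kernel=kernel, penalty_c=10.0, k=3, repeats=2, seed=0)
        assert res.accuracy_mean == 1.0

    def test_null_accuracy_near_chance(self):
        accs = []
        for seed in range(5):
            ds, _ = simulate_patterns(CohortConfig(n_subjects=6, trials_per_side=4, seed=40 + seed))
            res = cross_validate(ds, feature_mode="all_101", kernel=KernelSpec("linear"), k=3, repeats=1, seed=seed)
            accs.append(res.accuracy_mean)
        # pooled over 5 cohorts x 12 test patterns: binomial 3 SD band around 0.5
        assert abs(np.mean(accs) - 0.5) <= 3 * np.sqrt(0.25 / (5 * 12))

    def test_permuted_labels_kill_separability(self, asymmetric_cohort):
        dataset, _ = asymmetric_cohort
        work = subject_mean_patterns(dataset)
        rng = np.random.default_rng(5)
        # flip whole subjects' side labels: keeps folds balanced, destroys the signal
        flips = {s: rng.random() < 0.5 for s in {p.subject_id for p in work.patterns}}
        relabeled = [
            GaitPattern(
                p.subject_id,
                {"left": "right", "right": "left"}[p.side] if flips[p.subject_id] else p.side,
                p.trial_id,
                p.values,
            )
            for p in work.patterns
        ]
        res = cross_validate(
            GaitDataset(relabeled), feature_mode="all_101", kernel=KernelSpec("linear"),
            k=3, repeats=2, seed=1, aggregate="per_trial",
        )
        assert res.accuracy_mean <= 0.85  # far from the separable 1.0

    def test_no_leakage_from_test_fold(self, symmetric_cohort):
        dataset, _ = symmetric_cohort
        res = cross_validate(dataset, feature_mode="pca", kernel=KernelSpec("linear"), k=3, repeats=1, seed=9)
        work = subject_mean_patterns(dataset)
        # perturb one pattern and re-run: fold-mates' decisions must not move
        target = 0
        perturbed = []
        for i, p in enumerate(work.patterns):
            vals = p.values * 3.0 + 5.0 if i == target else p.values
            perturbed.append(GaitPattern(p.subject_id, p.side, p.trial_id, vals))
        res2 = cross_validate(
            GaitDataset(perturbed), feature_mode="pca", kernel=KernelSpec("linear"),
            k=3, repeats=1, seed=9, aggregate="per_trial",
        )
        pred1 = res.predictions.set_index("index")
        pred2 = res2.predictions.set_index("index")
        fold_of_target = pred1.loc[target, "fold"]
        mates = pred1[(pred1["fold"] == fold_of_target)].index.difference([target])
        assert len(mates) > 0
        np.testing.assert_allclose(
            pred1.loc[mates, "decision"], pred2.loc[mates, "decision"], atol=1e-10
        )

    def test_invariant_to_pattern_order_and_trial_ids(self, symmetric_cohort):
        dataset, _ = symmetric_cohort
        res = cross_validate(dataset, feature_mode="all_101", kernel=KernelSpec("linear"), k=3, repeats=1, seed=4)
        rng = np.random.default_rng(0)
        shuffled = list(dataset.patterns)
        rng.shuffle(shuffled)
        renamed = [
            GaitPattern(p.subject_id, p.side, f"renamed-{p.trial_id}", p.values) for p in shuffled
        ]
        res2 = cross_validate(
            GaitDataset(renamed), feature_mode="all_101", kernel=KernelSpec("linear"), k=3, repeats=1, seed=4
        )
        assert res.accuracy_mean == pytest.approx(res2.accuracy_mean, abs=1e-12)

    def test_records_shape_and_config_echo(self, symmetric_cohort):
        dataset, _ = symmetric_cohort
        res = cross_validate(dataset, feature_mode="six_params", kernel=KernelSpec("rbf", sigma=3.0),
                             penalty_c=2.0, k=2, repeats=3, seed=0)
        assert len(res.records) == 6
        assert res.config["kernel_kind"] == "rbf" and res.config["penalty_c"] == 2.0
        assert res.pooled_confusion().total == 3 * len(subject_mean_patterns(dataset))


class TestGridSearch:
    def test_single_point_grid_matches_cross_validate(self, asymmetric_cohort):
        dataset, _ = asymmetric_cohort
        kern = KernelSpec("linear")
        table = grid_search(dataset, [kern], [1.0], feature_modes=["all_101"], k=3, repeats=1, seed=2)
        assert len(table) == 1
        res = cross_validate(dataset, feature_mode="all_101", kernel=kern, penalty_c=1.0, k=3, repeats=1, seed=2)
        assert table.loc[0, "accuracy"] == pytest.approx(res.accuracy_mean)

    def test_separable_ties_break_by_smaller_c(self, asymmetric_cohort):
        dataset, _ = asymmetric_cohort
        table = grid_search(
            dataset, [KernelSpec("linear")], [10.0, 0.5, 2.0], feature_modes=["all_101"],
            k=3, repeats=1, seed=2,
        )
        assert table["accuracy"].eq(1.0).all()
        assert list(table["penalty_c"]) == [0.5, 2.0, 10.0]

    def test_comparison_table_renders_all_modes_and_kernels(self, asymmetric_cohort):
        dataset, _ = asymmetric_cohort
        kernels = [KernelSpec("linear"), KernelSpec("poly", degree=2), KernelSpec("rbf", sigma=5.0)]
        table = grid_search(dataset, kernels, [1.0], k=3, repeats=1, seed=0)
        text = render_comparison_table(table)
        for mode in ("all_101", "six_params", "pca"):
            assert mode in text
        assert text.count("(1.00, 1.00, 1.00)") >= 3
        best = best_per_feature_mode(table)
        assert len(best) == 3

    def test_empty_grid_rejected(self, symmetric_cohort):
        dataset, _ = symmetric_cohort
        with pytest.raises(GaitSymError):
            grid_search(dataset, [], [1.0])


class TestSymmetryScore:
    def test_score_mapping(self):
        assert score_from_accuracy(0.5) == 1.0
        assert score_from_accuracy(1.0) == 0.0
        assert score_from_accuracy(0.3) == 1.0  # below chance is still "symmetric"
        assert score_from_accuracy(0.75) == pytest.approx(0.5)

    def test_separable_cohort_detected(self, asymmetric_cohort):
        dataset, _ = asymmetric_cohort
        sc = symmetry_score(dataset, feature_mode="six_params", kernel=KernelSpec("linear"),
                            k=3, n_permutations=19, seed=0)
        assert sc.mean_accuracy == 1.0
        assert sc.score == 0.0
        assert sc.permutation_p <= 0.05

    def test_symmetric_cohort_not_detected(self, symmetric_cohort):
        dataset, _ = symmetric_cohort
        sc = symmetry_score(dataset, feature_mode="six_params", kernel=KernelSpec("linear"),
                            k=3, n_permutations=19, seed=1)
        assert sc.permutation_p > 0.05
        assert sc.score == pytest.approx(score_from_accuracy(sc.mean_accuracy))

    def test_low_permutation_count_warns(self, symmetric_cohort):
        dataset, _ = symmetric_cohort
        with pytest.warns(UserWarning, match="19"):
            symmetry_score(dataset, feature_mode="six_params", kernel=KernelSpec("linear"),
                           k=3, n_permutations=5, seed=0)
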