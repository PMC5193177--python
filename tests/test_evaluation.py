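"""Balanced subsampling, site-matched L2O, metrics, permutation machinery."""

import numpy as np
import pytest

from gmpredict.cohort import Cohort, Subject
from gmpredict.evaluation import (
    ConfusionCounts,
    EvaluationError,
    balanced_subsample,
    bootstrap_ensemble,
    compute_metrics,
    leave_two_out_cv,
    permutation_p,
    permutation_test,
)
from gmpredict.imaging import FeatureMatrix, VoxelMask


def build_cohort(layout):
    """layout: list of (site, course, n) -> male subjects with that label."""
    subjects = []
    i = 0
    for site, course, n in layout:
        for _ in range(n):
            subjects.append(
                Subject(subject_id=f"s{i:03d}", site=site, sex="male", course_label=course)
            )
            i += 1
    return Cohort(tuple(subjects))


def features_for(cohort, rng, signal=0.0):
    """Random features with an optional course signal in the first column."""
    mask = VoxelMask(np.ones((4, 4, 4), dtype=bool), 0.0)
    X = rng.normal(0, 1, size=(len(cohort), 64))
    for i, s in enumerate(cohort):
        if s.course_label == "continuous":
            X[i, :8] += signal
    return FeatureMatrix(X, tuple(s.subject_id for s in cohort), mask)


class TestMetrics:
    def test_formulas_on_hand_counted_confusion(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert m.ppa == pytest.approx(0.75)
        assert m.npa == pytest.approx(4 / 6)
        assert m.pos_class_accuracy == pytest.approx(3 / 5)
        assert m.neg_class_accuracy == pytest.approx(4 / 5)

    def test_no_false_positives_gives_perfect_ppa(self):
        assert compute_metrics(ConfusionCounts(tp=5, fp=0, tn=1, fn=1)).ppa == 1.0

    def test_zero_denominator_is_undefined_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert m.ppa is None
        assert m.npa == pytest.approx(0.6)

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestPermutationP:
    def test_all_null_below_observed_gives_zero(self):
        assert permutation_p(1.0, [0.5, 0.6, 0.7]) == 0.0

    def test_ties_count_as_extreme(self):
        assert permutation_p(0.8, [0.8, 0.8, 0.8]) == 1.0

    def test_smoothed_variant_cannot_be_zero(self):
        assert permutation_p(1.0, [0.5] * 4, smoothed=True) == pytest.approx(1 / 5)

    def test_invariant_to_monotone_transformation(self, rng):
        null = rng.normal(size=200)
        obs = 0.3
        p1 = permutation_p(obs, null)
        p2 = permutation_p(np.exp(obs), np.exp(null))
        assert p1 == p2


class TestBalancedSubsample:
    def test_site_keeps_minority_and_matches_majority(self, rng):
        cohort = build_cohort([("utrecht", "continuous", 58), ("utrecht", "remitting", 9)])
        sub = balanced_subsample(cohort, "course_label", seed=4)
        labels = [s.course_label for s in sub]
        assert len(sub) == 18
        assert labels.count("remitting") == 9 and labels.count("continuous") == 9

    def test_already_balanced_cohort_unchanged(self):
        cohort = build_cohort([("a", "continuous", 5), ("a", "remitting", 5)])
        sub = balanced_subsample(cohort, "course_label", seed=0)
        assert set(s.subject_id for s in sub) == set(s.subject_id for s in cohort)

    def test_every_majority_member_selected_at_least_once_over_seeds(self):
        cohort = build_cohort([("a", "continuous", 12), ("a", "remitting", 4)])
        seen = set()
        for seed in range(200):
            sub = balanced_subsample(cohort, "course_label", seed=seed)
            seen |= {s.subject_id for s in sub if s.course_label == "continuous"}
        majority_ids = {s.subject_id for s in cohort if s.course_label == "continuous"}
        assert seen == majority_ids

    def test_cross_site_deficit_drawn_from_other_sites(self):
        # site b has more minority (remitting) than majority (continuous):
        # the shortfall must come from site a's unselected continuous pool
        cohort = build_cohort(
            [("a", "continuous", 10), ("a", "remitting", 2),
             ("b", "continuous", 1), ("b", "remitting", 6)]
        )
        sub = balanced_subsample(cohort, "course_label", seed=1)
        labels = [s.course_label for s in sub]
        assert labels.count("continuous") == labels.count("remitting") == 8

    def test_single_class_rejected(self):
        cohort = build_cohort([("a", "continuous", 4)])
        with pytest.raises(EvaluationError):
            balanced_subsample(cohort, "course_label", seed=0)

    def test_preserves_input_order(self):
        cohort = build_cohort([("a", "continuous", 6), ("a", "remitting", 6)])
        sub = balanced_subsample(cohort, "course_label", seed=3)
        ids = [s.subject_id for s in sub]
        assert ids == sorted(ids)


class TestLeaveTwoOut:
    def test_single_site_three_per_class_accounting(self, rng):
        cohort = build_cohort([("a", "continuous", 3), ("a", "remitting", 3)])
        res = leave_two_out_cv(cohort, features_for(cohort, rng), "course_label",
                               c_grid=(1.0,), seed=0)
        assert (res.per_subject.times_tested == 1).all()
        assert res.confusion.total == 6
        assert res.class_labels == ("remitting", "continuous")

    def test_unpaired_remainder_not_tested(self, rng):
        cohort = build_cohort([("a", "continuous", 4), ("a", "remitting", 3)])
        res = leave_two_out_cv(cohort, features_for(cohort, rng), "course_label",
                               c_grid=(1.0,), seed=0)
        tested = res.per_subject.times_tested
        assert tested.sum() == 6 and (tested <= 1).all()
        untested = res.per_subject[tested == 0]
        assert list(untested.true_label) == ["continuous"]

    def test_confusion_matches_brute_force_recount(self, rng):
        cohort = build_cohort([("a", "continuous", 5), ("a", "remitting", 5),
                               ("b", "continuous", 4), ("b", "remitting", 4)])
        res = leave_two_out_cv(cohort, features_for(cohort, rng, signal=0.5),
                               "course_label", c_grid=(1.0,), seed=7)
        assert res.confusion == res.recount_confusion()

    def test_site_isolation_of_pairing(self, rng):
        """Dropping one site entirely leaves the other site's held-out pair
        composition unchanged (same per-site seeds)."""
        cohort = build_cohort([("a", "continuous", 4), ("a", "remitting", 4),
                               ("b", "continuous", 3), ("b", "remitting", 3)])
        feats = features_for(cohort, rng)
        full = leave_two_out_cv(cohort, feats, "course_label", c_grid=(1.0,), seed=5)
        only_a_idx = [i for i, s in enumerate(cohort) if s.site == "a"]
        sub = cohort.subset(only_a_idx)
        alone = leave_two_out_cv(sub, feats, "course_label", c_grid=(1.0,), seed=5)

        def pairs_of(res, site):
            t = res.per_subject[(res.per_subject.site == site)]
            return set(t[t.times_tested > 0].subject_id)

        assert pairs_of(full, "a") == pairs_of(alone, "a")

    def test_deterministic_under_seed(self, rng):
        cohort = build_cohort([("a", "continuous", 4), ("a", "remitting", 4)])
        feats = features_for(cohort, rng, signal=1.0)
        r1 = leave_two_out_cv(cohort, feats, "course_label", seed=9, c_grid=(0.1, 1.0))
        r2 = leave_two_out_cv(cohort, feats, "course_label", seed=9, c_grid=(0.1, 1.0))
        assert r1.per_subject.equals(r2.per_subject)
        assert r1.selected_C == r2.selected_C

    def test_strong_signal_recovered(self, rng):
        cohort = build_cohort([("a", "continuous", 8), ("a", "remitting", 8)])
        feats = features_for(cohort, rng, signal=3.0)
        res = leave_two_out_cv(cohort, feats, "course_label", c_grid=(1.0,), seed=2)
        assert res.metrics.balanced_accuracy >= 0.9


class TestBootstrapEnsemble:
    def test_single_bootstrap_equals_its_run(self, rng):
        cohort = build_cohort([("a", "continuous", 4), ("a", "remitting", 4)])
        feats = features_for(cohort, rng, signal=2.0)
        ens = bootstrap_ensemble(cohort, feats, "course_label", n_bootstraps=1,
                                 seed=3, c_grid=(1.0,))
        run = ens.per_bootstrap[0]
        assert ens.mean_metrics["balanced_accuracy"] == run.metrics.balanced_accuracy

    def test_identical_seeds_identical_results(self, rng):
        cohort = build_cohort([("a", "continuous", 5), ("a", "remitting", 4)])
        feats = features_for(cohort, rng, signal=1.0)
        e1 = bootstrap_ensemble(cohort, feats, "course_label", n_bootstraps=3,
                                seed=11, c_grid=(1.0,))
        e2 = bootstrap_ensemble(cohort, feats, "course_label", n_bootstraps=3,
                                seed=11, c_grid=(1.0,))
        assert e1.mean_metrics == e2.mean_metrics
        assert e1.per_site == e2.per_site

    def test_mean_metrics_are_arithmetic_means(self, rng):
        cohort = build_cohort([("a", "continuous", 6), ("a", "remitting", 4)])
        feats = features_for(cohort, rng, signal=1.0)
        ens = bootstrap_ensemble(cohort, feats, "course_label", n_bootstraps=4,
                                 seed=2, c_grid=(1.0,))
        per_run = [r.metrics.balanced_accuracy for r in ens.per_bootstrap]
        assert ens.mean_metrics["balanced_accuracy"] == pytest.approx(np.mean(per_run))


class TestPermutationTest:
    def test_counting_rule_and_determinism(self, rng):
        cohort = build_cohort([("a", "continuous", 5), ("a", "remitting", 5)])
        feats = features_for(cohort, rng, signal=4.0)
        res = permutation_test(cohort, feats, "course_label", n_permutations=20,
                               seed=6, c_grid=(1.0,))
        assert res.observed == pytest.approx(1.0)
        expected_p = permutation_p(res.observed, res.null_values)
        assert res.p_value == expected_p
        res2 = permutation_test(cohort, feats, "course_label", n_permutations=20,
                                seed=6, c_grid=(1.0,))
        assert res.null_values == res2.null_values

    def test_null_distribution_centers_at_chance(self, rng):
        cohort = build_cohort([("a", "continuous", 6), ("a", "remitting", 6),
                               ("b", "continuous", 6), ("b", "remitting", 6)])
        feats = features_for(cohort, rng, signal=0.0)
        res = permutation_test(cohort, feats, "course_label", n_permutations=100,
                               seed=1, c_grid=(1.0,))
        assert abs(np.mean(res.null_values) - 0.5) < 0.05
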