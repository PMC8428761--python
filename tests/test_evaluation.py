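"""Stratified partition, bilateral fusion, metrics, and the CV driver."""

import dataclasses

import numpy as np
import pytest

import wristrf as w
from wristrf.evaluation import METRIC_NAMES

# ---------------------------------------------------------------------------
# Stratified partition
# ---------------------------------------------------------------------------


def _labels(n1, n2):
    out = {f"a{i:04d}": w.GROUP1 for i in range(n1)}
    out.update({f"b{i:04d}": w.GROUP2 for i in range(n2)})
    return out


class TestStratifiedPartition:
    def test_study_layout_gives_subsets_of_9_or_10(self):
        fold = w.stratified_partition(_labels(27, 40), k=7, seed=0)
        sizes = sorted(len(fold.subset(i)) for i in range(7))
        assert sizes == [9, 9, 9, 10, 10, 10, 10]

    def test_study_layout_class_balance(self):
        labels = _labels(27, 40)
        fold = w.stratified_partition(labels, k=7, seed=3)
        for i in range(7):
            members = fold.subset(i)
            n1 = sum(1 for sid in members if labels[sid] == w.GROUP1)
            assert n1 in (3, 4)
            assert len(members) - n1 in (5, 6)

    def test_two_by_two_is_forced(self):
        labels = _labels(2, 2)
        fold = w.stratified_partition(labels, k=2, seed=1)
        for i in range(2):
            members = fold.subset(i)
            assert sorted(labels[sid] for sid in members) == [w.GROUP1, w.GROUP2]

    def test_membership_is_total_partition(self):
        labels = _labels(13, 19)
        fold = w.stratified_partition(labels, k=5, seed=2)
        assert set(fold.membership) == set(labels)
        assert set(fold.membership.values()) <= set(range(5))
        assert sum(len(fold.subset(i)) for i in range(5)) == 32

    def test_invariants_hold_over_random_draws(self):
        """Sizes within 1 and class counts within 1 of proportionality for
        500 random (n1, n2, k, seed) draws."""
        rng = np.random.default_rng(12345)
        for _ in range(500):
            n1 = int(rng.integers(2, 60))
            n2 = int(rng.integers(2, 60))
            k = int(rng.integers(2, min(n1, n2) + 1))
            labels = _labels(n1, n2)
            fold = w.stratified_partition(labels, k=k, seed=int(rng.integers(0, 2**31)))
            sizes = np.array([len(fold.subset(i)) for i in range(k)])
            assert sizes.max() - sizes.min() <= 1
            for cls, total in ((w.GROUP1, n1), (w.GROUP2, n2)):
                counts = np.array([
                    sum(1 for sid in fold.subset(i) if labels[sid] == cls)
                    for i in range(k)
                ])
                expected = total * sizes / (n1 + n2)
                assert np.max(np.abs(counts - expected)) <= 1.0 + 1e-9

    def test_seed_changes_partition_not_sizes(self):
        labels = _labels(27, 40)
        a = w.stratified_partition(labels, k=7, seed=0)
        b = w.stratified_partition(labels, k=7, seed=1)
        assert a.membership != b.membership
        assert sorted(len(a.subset(i)) for i in range(7)) == sorted(
            len(b.subset(i)) for i in range(7)
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            w.stratified_partition(_labels(2, 2), k=5, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            w.stratified_partition({f"s{i}": w.GROUP1 for i in range(6)}, k=2, seed=0)


# ---------------------------------------------------------------------------
# Bilateral fusion
# ---------------------------------------------------------------------------

# independently written truth table: (left, right, scheme) -> fused label
_G1, _G2 = w.GROUP1, w.GROUP2
_FUSION_ORACLE = {
    (_G1, _G1, "keep_left"): _G1,
    (_G1, _G1, "keep_right"): _G1,
    (_G1, _G1, "keep_osteo"): _G1,
    (_G1, _G1, "keep_healthy"): _G1,
    (_G2, _G2, "keep_left"): _G2,
    (_G2, _G2, "keep_right"): _G2,
    (_G2, _G2, "keep_osteo"): _G2,
    (_G2, _G2, "keep_healthy"): _G2,
    (_G1, _G2, "keep_left"): _G1,
    (_G1, _G2, "keep_right"): _G2,
    (_G1, _G2, "keep_osteo"): _G1,
    (_G1, _G2, "keep_healthy"): _G2,
    (_G2, _G1, "keep_left"): _G2,
    (_G2, _G1, "keep_right"): _G1,
    (_G2, _G1, "keep_osteo"): _G1,
    (_G2, _G1, "keep_healthy"): _G2,
}


class TestFusion:
    def test_all_sixteen_cases_match_oracle(self):
        assert len(_FUSION_ORACLE) == 16
        for (left, right, scheme), expected in _FUSION_ORACLE.items():
            assert w.fuse_arm_predictions(left, right, scheme) == expected

    def test_agreement_overrides_scheme(self):
        assert w.fuse_arm_predictions(_G1, _G1, "keep_healthy") == _G1

    def test_separate_is_a_contract_error(self):
        with pytest.raises(ValueError, match="separate"):
            w.fuse_arm_predictions(_G1, _G2, "separate")

    def test_unknown_inputs_rejected(self):
        with pytest.raises(ValueError):
            w.fuse_arm_predictions(_G1, _G2, "majority")
        with pytest.raises(ValueError):
            w.fuse_arm_predictions("x", _G2, "keep_left")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _brute_force_metrics(pairs):
    tp = sum(1 for p, t in pairs if t == _G1 and p == _G1)
    fn = sum(1 for p, t in pairs if t == _G1 and p == _G2)
    tn = sum(1 for p, t in pairs if t == _G2 and p == _G2)
    fp = sum(1 for p, t in pairs if t == _G2 and p == _G1)
    out = {}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    out["accuracy"] = (tp + tn) / len(pairs) if pairs else None
    if out["sensitivity"] is not None and out["specificity"] is not None:
        out["youden_j"] = out["sensitivity"] + out["specificity"] - 1.0
    else:
        out["youden_j"] = None
    return out


class TestMetrics:
    def test_agrees_with_brute_force_recounts(self):
        """1,000 random (prediction, truth) tallies recomputed from raw pairs."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            pairs = [
                (
                    _G1 if rng.random() < 0.5 else _G2,
                    _G1 if rng.random() < 0.4 else _G2,
                )
                for _ in range(n)
            ]
            counts = w.ConfusionCounts.from_pairs(pairs)
            expected = _brute_force_metrics(pairs)
            got = w.compute_metrics(counts)
            for name in METRIC_NAMES:
                if expected[name] is None:
                    assert got[name] is None
                else:
                    assert got[name] == pytest.approx(expected[name], abs=1e-12)

    def test_headline_rate_arithmetic(self):
        got = w.compute_metrics(w.ConfusionCounts(tp=83, fn=17, tn=94, fp=6))
        assert got["sensitivity"] == pytest.approx(0.83)
        assert got["specificity"] == pytest.approx(0.94)
        assert got["youden_j"] == pytest.approx(0.77)

    def test_perfect_and_chance_classifiers(self):
        perfect = w.compute_metrics(w.ConfusionCounts(tp=10, fn=0, tn=20, fp=0))
        assert all(perfect[m] == 1.0 for m in ("sensitivity", "specificity", "accuracy", "youden_j"))
        chance = w.compute_metrics(w.ConfusionCounts(tp=5, fn=5, tn=8, fp=8))
        assert chance["youden_j"] == pytest.approx(0.0)

    def test_empty_denominator_is_undefined_not_zero(self):
        got = w.compute_metrics(w.ConfusionCounts(tp=0, fn=0, tn=9, fp=1))
        assert got["sensitivity"] is None
        assert got["youden_j"] is None
        assert got["specificity"] == pytest.approx(0.9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            w.ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


# ---------------------------------------------------------------------------
# CV driver
# ---------------------------------------------------------------------------


class TestRunCV:
    def test_separate_mode_produces_134_arm_predictions(self, study_cohort, fast_config):
        recipe = w.FeatureRecipe("magnitude", "separate", False, False)
        result = w.run_cv(study_cohort, recipe, classifier_config=fast_config, k=7, seed=0)
        totals = sum(c.total for c in result.per_scheme["separate"])
        assert totals == 134

    def test_fused_blocks_cover_67_subjects(self, study_cohort, fast_config):
        recipe = w.FeatureRecipe("magnitude", "separate", False, False)
        result = w.run_cv(study_cohort, recipe, classifier_config=fast_config, k=7, seed=0)
        for scheme in ("keep_left", "keep_right", "keep_osteo", "keep_healthy"):
            assert sum(c.total for c in result.per_scheme[scheme]) == 67

    def test_no_subject_splits_across_folds(self, study_cohort, fast_config):
        recipe = w.FeatureRecipe("magnitude", "separate", False, False)
        result = w.run_cv(study_cohort, recipe, classifier_config=fast_config, k=7, seed=1)
        membership = result.fold_assignment.membership
        assert set(membership) == {s.subject_id for s in study_cohort}

    def test_non_separate_mode_yields_single_subject_block(self, small_cohort):
        recipe = w.FeatureRecipe("magnitude", "average", False, False)
        config = w.ClassifierConfig(n_in=21, n_hidden=3, epochs=20, seed=0)
        result = w.run_cv(small_cohort, recipe, classifier_config=config, k=3, seed=0)
        assert list(result.per_scheme) == ["subject"]
        assert sum(c.total for c in result.per_scheme["subject"]) == len(small_cohort)

    def test_leave_one_subject_out_boundary(self, small_cohort):
        recipe = w.FeatureRecipe("magnitude", "average", False, False)
        config = w.ClassifierConfig(n_in=21, n_hidden=3, epochs=10, seed=0)
        n = len(small_cohort)
        result = w.run_cv(small_cohort, recipe, classifier_config=config, k=n, seed=0)
        assert all(c.total == 1 for c in result.per_scheme["subject"])

    def test_single_class_training_fold_is_an_error(self):
        cohort = w.simulate_cohort(
            w.SimulationParams(n_group1=1, n_group2=9, n_points=11, seed=2)
        )
        recipe = w.FeatureRecipe("magnitude", "average", False, False)
        config = w.ClassifierConfig(n_in=11, n_hidden=2, epochs=5, seed=0)
        with pytest.raises(ValueError, match="single class"):
            w.run_cv(cohort, recipe, classifier_config=config, k=2, seed=0)

    def test_unknown_group_subjects_rejected(self, small_cohort):
        subj = dataclasses.replace(small_cohort.subjects[0], group=w.UNKNOWN)
        cohort = w.Cohort(subjects=[subj] + small_cohort.subjects[1:])
        with pytest.raises(ValueError, match="unknown group"):
            w.run_cv(cohort, w.FeatureRecipe("magnitude", "average", False, False), k=2)

    def test_mean_excludes_undefined_fold_metrics_with_warning(self):
        result = w.CVResult(
            k=2,
            seed=0,
            recipe=w.FeatureRecipe("magnitude", "average", False, False),
            fold_assignment=w.FoldAssignment(k=2, membership={"a": 0, "b": 1}, seed=0),
            per_scheme={
                "subject": [
                    w.ConfusionCounts(tp=2, fn=0, tn=3, fp=1),  # defined
                    w.ConfusionCounts(tp=0, fn=0, tn=4, fp=0),  # no positives
                ]
            },
        )
        with pytest.warns(UserWarning, match="undefined"):
            means = result.mean_metrics("subject")
        assert means["sensitivity"] == pytest.approx(1.0)  # only the defined fold
        assert means["specificity"] == pytest.approx((0.75 + 1.0) / 2)

    def test_result_serializes_with_config_echo(self, small_cohort):
        recipe = w.FeatureRecipe("magnitude", "average", False, False)
        config = w.ClassifierConfig(n_in=21, n_hidden=3, epochs=10, seed=0)
        result = w.run_cv(small_cohort, recipe, classifier_config=config, k=3, seed=5)
        d = result.to_dict()
        assert d["recipe"]["encoding"] == "magnitude"
        assert d["k"] == 3 and d["seed"] == 5
        assert len(d["folds"]) == len(small_cohort)
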