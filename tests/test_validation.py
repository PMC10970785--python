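"""Tests for splits, cross-validation, controls, learning curves and metrics."""

import numpy as np
import pytest

from ambientms.validation import (concordance, event_level_split, learning_curve,
                                  leave_p_out_cv, metrics, permuted_mixed_model,
                                  pseudo_class_control, specimen_aware_split)


def _cohort(n_classes=3, specimens=5, events=4):
    labels, specs = [], []
    for c in range(n_classes):
        for s in range(specimens):
            labels += [f"c{c}"] * events
            specs += [f"c{c}_s{s}"] * events
    return np.array(specs), np.array(labels)


class TestSpecimenAwareSplit:
    def test_holdout_counts_follow_rounding(self):
        specs, labels = _cohort(specimens=10)
        train, test = specimen_aware_split(specs, labels, 0.2, seed=1)
        for c in np.unique(labels):
            held = np.unique(specs[test][labels[test] == c])
            assert held.size == 2  # round(0.2 * 10)

    def test_no_specimen_on_both_sides(self):
        specs, labels = _cohort()
        for seed in range(20):
            train, test = specimen_aware_split(specs, labels, 0.3, seed=seed)
            assert not set(specs[train]) & set(specs[test])
            assert len(train) + len(test) == len(specs)

    def test_seed_contract(self):
        specs, labels = _cohort()
        a = specimen_aware_split(specs, labels, 0.2, seed=5)
        b = specimen_aware_split(specs, labels, 0.2, seed=5)
        c = specimen_aware_split(specs, labels, 0.2, seed=6)
        np.testing.assert_array_equal(a[1], b[1])
        assert not np.array_equal(a[1], c[1])

    def test_single_specimen_class_raises(self):
        specs = np.array(["a1", "a1", "b1", "b1"])
        labels = np.array(["A", "A", "B", "B"])
        with pytest.raises(ValueError):
            specimen_aware_split(specs, labels, 0.2, seed=0)

    def test_fraction_bounds(self):
        specs, labels = _cohort()
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                specimen_aware_split(specs, labels, bad, seed=0)

    def test_event_split_is_stratified(self):
        specs, labels = _cohort()
        train, test = event_level_split(labels, 0.25, seed=0)
        for c in np.unique(labels):
            assert (labels[test] == c).sum() == 5  # round(0.25 * 20)


class TestPermutedMixedModel:
    def test_equal_composition_small_case(self):
        labels = np.array(["A"] * 4 + ["B"] * 4)
        pseudo = permuted_mixed_model(labels, seed=0)
        for p in ("A", "B"):
            from_a = np.sum((pseudo == p) & (labels == "A"))
            from_b = np.sum((pseudo == p) & (labels == "B"))
            assert from_a == 2 and from_b == 2

    def test_composition_within_one_of_equal_share(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["A", "B", "C"], size=200)
        pseudo = permuted_mixed_model(labels, seed=4)
        for true_c in "ABC":
            n_true = (labels == true_c).sum()
            for p in "ABC":
                got = np.sum((pseudo == p) & (labels == true_c))
                assert abs(got - n_true / 3) <= 1

    def test_spectra_untouched_same_event_set(self):
        labels = np.array(["A"] * 6 + ["B"] * 6)
        pseudo = permuted_mixed_model(labels, seed=1)
        assert sorted(pseudo) == sorted(labels)

    def test_blocked_variant_keeps_specimens_together(self):
        specs, labels = _cohort(n_classes=2, specimens=6, events=3)
        pseudo = permuted_mixed_model(labels, seed=2, specimens=specs,
                                      blocked=True)
        for s in np.unique(specs):
            assert np.unique(pseudo[specs == s]).size == 1

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            permuted_mixed_model(np.array(["A", "A"]))


class TestPseudoClassControl:
    def test_realistic_cohort_sizes_near_equal(self):
        labels = pseudo_class_control(409, 3, seed=0)
        _, counts = np.unique(labels, return_counts=True)
        assert sorted(counts) == [136, 136, 137]

    def test_degenerate_k_rejected(self):
        with pytest.raises(ValueError):
            pseudo_class_control(10, 10, seed=0)
        with pytest.raises(ValueError):
            pseudo_class_control(10, 1, seed=0)

    def test_seeded_assignment(self):
        a = pseudo_class_control(20, 4, seed=7)
        b = pseudo_class_control(20, 4, seed=7)
        np.testing.assert_array_equal(a, b)


class TestLeavePOutCV:
    def test_report_is_reproducible(self, small_prepared):
        p = small_prepared
        kw = dict(p=0.2, repeats=3, seed=9, threshold=0.0)
        r1 = leave_p_out_cv(p.X, p.y, p.specimens, **kw)
        r2 = leave_p_out_cv(p.X, p.y, p.specimens, **kw)
        np.testing.assert_array_equal(r1.confusion_matrix, r2.confusion_matrix)
        assert r1.accuracy == r2.accuracy
        assert r1.fold_assignments == r2.fold_assignments

    def test_confusion_and_duty_accounting(self, small_prepared):
        p = small_prepared
        r = leave_p_out_cv(p.X, p.y, p.specimens, repeats=4, seed=2)
        total_attempts = r.confusion_matrix.sum() + r.unclassified_count
        assert r.duty_cycle == pytest.approx(
            r.confusion_matrix.sum() / total_attempts)
        assert r.accuracy == pytest.approx(
            np.trace(r.confusion_matrix) / r.confusion_matrix.sum())
        assert len(r.pc_caps) == 4

    def test_unbalanced_design_warns(self, small_prepared):
        p = small_prepared
        keep = np.ones(len(p.y), dtype=bool)
        drop_class = p.y == p.y[0]
        keep[np.flatnonzero(drop_class)[:20]] = False
        with pytest.warns(UserWarning, match="unbalanced"):
            leave_p_out_cv(p.X[keep], p.y[keep], p.specimens[keep],
                           repeats=1, seed=0)

    def test_well_separated_data_classified_correctly(self, small_prepared):
        p = small_prepared
        r = leave_p_out_cv(p.X, p.y, p.specimens, repeats=5, seed=3)
        assert r.accuracy > 0.9
        assert r.kappa > 0.8
        assert np.all(r.auroc_ovr > 0.9)


class TestLearningCurve:
    def test_full_usage_point_matches_plain_cv(self, small_prepared):
        p = small_prepared
        seed = 31
        result = learning_curve(p.X, p.y, p.specimens, usage_fractions=[1.0],
                                repeats=2, seed=seed)
        cv_seed = int(np.random.default_rng(seed).integers(0, 2 ** 31 - 1))
        direct = leave_p_out_cv(p.X, p.y, p.specimens, p=0.2, repeats=2,
                                seed=cv_seed)
        assert result.accuracies[0] == direct.accuracy
        assert result.pc_caps[0] == max(direct.pc_caps)

    def test_fixed_rule_caps_components(self, small_prepared):
        p = small_prepared
        result = learning_curve(p.X, p.y, p.specimens,
                                usage_fractions=[0.5, 1.0], pc_rule=5,
                                repeats=2, seed=1)
        assert all(c <= 5 for c in result.pc_caps)

    def test_specimen_subsample_counts(self, small_prepared):
        p = small_prepared
        result = learning_curve(p.X, p.y, p.specimens,
                                usage_fractions=[0.5, 1.0], repeats=2, seed=2,
                                subsample_mode="specimen")
        assert result.specimens_used == [6, 12]  # 2 classes x {3, 6}

    def test_unknown_rules_raise(self, small_prepared):
        p = small_prepared
        with pytest.raises(ValueError):
            learning_curve(p.X, p.y, p.specimens, pc_rule="magic", repeats=1)
        with pytest.raises(ValueError):
            learning_curve(p.X, p.y, p.specimens, subsample_mode="nope",
                           repeats=1)


class TestMetrics:
    def test_diagonal_matrix_is_perfect(self):
        m = metrics(np.diag([5, 7, 9]))
        assert m.kappa == pytest.approx(1.0)
        np.testing.assert_allclose(m.sensitivity, 1.0)
        np.testing.assert_allclose(m.specificity, 1.0)

    def test_hand_computed_kappa(self):
        # p_o = 0.7, p_e = 0.5 -> kappa 0.4
        m = metrics([[40, 10], [20, 30]])
        assert m.kappa == pytest.approx(0.4)
        assert m.sensitivity[0] == pytest.approx(0.8)
        assert m.specificity[0] == pytest.approx(0.6)

    def test_kappa_matches_sklearn_on_random_matrices(self, rng):
        from sklearn.metrics import cohen_kappa_score
        for _ in range(30):
            C = rng.integers(0, 40, size=(4, 4))
            if C.sum() == 0 or C.sum(axis=1).min() == 0:
                continue
            y_true = np.repeat(np.arange(4), C.sum(axis=1))
            y_pred = np.concatenate([np.repeat(np.arange(4), row) for row in C])
            try:
                ours = metrics(C).kappa
            except ValueError:
                continue
            expected = cohen_kappa_score(y_true, y_pred)
            assert ours == pytest.approx(expected, abs=1e-10)

    def test_auroc_matches_sklearn_with_ties(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(30):
            truth = rng.choice(["a", "b", "c"], size=60)
            if np.unique(truth).size < 3:
                continue
            scores = np.round(rng.uniform(size=(60, 3)), 1)  # force ties
            m = metrics(np.eye(3), scores=scores, truth=truth,
                        classes=["a", "b", "c"])
            for i, c in enumerate(["a", "b", "c"]):
                expected = roc_auc_score((truth == c).astype(int), scores[:, i])
                assert m.auroc_ovr[i] == pytest.approx(expected, abs=1e-10)

    def test_auroc_limits(self):
        truth = np.array(["a"] * 5 + ["b"] * 5)
        perfect = np.column_stack([np.r_[np.ones(5), np.zeros(5)],
                                   np.r_[np.zeros(5), np.ones(5)]])
        m = metrics(np.eye(2), scores=perfect, truth=truth, classes=["a", "b"])
        np.testing.assert_allclose(m.auroc_ovr, 1.0)
        flat = np.full((10, 2), 0.5)
        m = metrics(np.eye(2), scores=flat, truth=truth, classes=["a", "b"])
        np.testing.assert_allclose(m.auroc_ovr, 0.5)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            metrics(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            metrics([[3, 0], [0, 0]])  # p_e = 1 in strict mode
        assert metrics([[3, 0], [0, 0]], strict=False).kappa is None


class TestConcordance:
    def test_unanimous_specimen(self):
        mean, per = concordance({"s1": ["A", "A", "A"]})
        assert mean == 1.0 and per["s1"] == 1.0

    def test_majority_fraction(self):
        mean, per = concordance({"s1": ["A", "A", "B"]})
        assert per["s1"] == pytest.approx(2 / 3)

    def test_sparse_specimens_excluded(self):
        mean, per = concordance({"s1": ["A"], "s2": ["B", "B"]})
        assert "s1" not in per
        assert mean == 1.0

    def test_empty_input(self):
        mean, per = concordance({})
        assert mean is None and per == {}
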