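"""Subject-wise splits, confusion metrics, and paired statistics."""

import itertools

import numpy as np
import pytest

from imugait.evaluate import (ConfusionCounts, StatTestResult, accuracy,
                              all_sensor_subsets, compare_paired, confusion,
                              make_split, per_class_accuracy, recall,
                              repeated_splits)
from imugait.io import ValidationError


class TestSplits:
    def test_19_subjects_split_11_4_4(self):
        plan = make_split([f"s{i}" for i in range(19)], seed=0)
        assert (len(plan.train_subjects), len(plan.val_subjects),
                len(plan.test_subjects)) == (11, 4, 4)

    def test_5_subjects_split_3_1_1(self):
        plan = make_split([f"s{i}" for i in range(5)], seed=0)
        assert (len(plan.train_subjects), len(plan.val_subjects),
                len(plan.test_subjects)) == (3, 1, 1)

    def test_determinism_and_disjointness(self):
        ids = [f"s{i}" for i in range(12)]
        a = make_split(ids, seed=7)
        b = make_split(ids, seed=7)
        assert a == b
        groups = [set(a.train_subjects), set(a.val_subjects),
                  set(a.test_subjects)]
        assert set().union(*groups) == set(ids)
        for g1, g2 in itertools.combinations(groups, 2):
            assert not g1 & g2

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            make_split(["a", "b"], seed=0)

    def test_repeated_splits_vary(self):
        ids = [f"s{i}" for i in range(19)]
        plans = repeated_splits(ids, n_repeats=10, base_seed=0)
        assert len(plans) == 10
        test_sets = {plan.test_subjects for plan in plans}
        assert len(test_sets) >= 2


def _brute_confusion(y_true, y_pred, n_classes):
    """Independent double-loop oracle for one-vs-rest counts."""
    tp = [0] * n_classes
    tn = [0] * n_classes
    fp = [0] * n_classes
    fn = [0] * n_classes
    for c in range(n_classes):
        for t, p in zip(y_true, y_pred):
            if t == c and p == c:
                tp[c] += 1
            elif t == c:
                fn[c] += 1
            elif p == c:
                fp[c] += 1
            else:
                tn[c] += 1
    return tp, tn, fp, fn


class TestConfusionMetrics:
    def test_hand_counted_example(self):
        c = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert (c.tp[0], c.fn[0], c.fp[0], c.tn[0]) == (1, 1, 0, 2)
        assert accuracy(c) == 0.75

    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 3, 4] * 3)
        c = confusion(y, y, 5)
        assert (c.fp == 0).all() and (c.fn == 0).all()
        assert accuracy(c) == 1.0 and recall(c) == 1.0

    def test_macro_recall_hand_example(self):
        c = confusion([0, 1, 2, 2], [0, 1, 2, 1], 3)
        assert recall(c) == pytest.approx(5 / 6)

    def test_counts_sum_to_total_per_class(self, rng):
        y_true = rng.integers(0, 5, size=200)
        y_pred = rng.integers(0, 5, size=200)
        c = confusion(y_true, y_pred, 5)
        totals = c.tp + c.tn + c.fp + c.fn
        assert (totals == 200).all()

    def test_matches_bruteforce_oracle_on_random_vectors(self, rng):
        for _ in range(10):
            n_classes = int(rng.integers(2, 6))
            n = int(rng.integers(5, 60))
            y_true = rng.integers(0, n_classes, size=n)
            # ensure every class occurs so macro recall is defined
            y_true[:n_classes] = np.arange(n_classes)
            y_pred = rng.integers(0, n_classes, size=n)
            c = confusion(y_true, y_pred, n_classes)
            tp, tn, fp, fn = _brute_confusion(y_true, y_pred, n_classes)
            assert list(c.tp) == tp and list(c.tn) == tn
            assert list(c.fp) == fp and list(c.fn) == fn
            brute_acc = sum(t == p for t, p in zip(y_true, y_pred)) / n
            assert accuracy(c) == pytest.approx(brute_acc)
            brute_rec = np.mean([tp[k] / (tp[k] + fn[k])
                                 for k in range(n_classes)])
            assert recall(c) == pytest.approx(brute_rec)

    def test_random_labels_accuracy_near_chance(self, rng):
        n = 20000
        y_true = rng.integers(0, 5, size=n)
        y_pred = rng.integers(0, 5, size=n)
        acc = accuracy(confusion(y_true, y_pred, 5))
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(acc - 0.2) < 3 * se

    def test_per_class_accuracy_one_vs_rest(self):
        c = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_allclose(per_class_accuracy(c), [0.75, 0.75])


def _exact_wilcoxon_p(diffs):
    """Full 2^n sign-enumeration oracle for the signed-rank test."""
    diffs = np.asarray([d for d in diffs if d != 0], dtype=float)
    n = len(diffs)
    ranks = np.empty(n)
    order = np.argsort(np.abs(diffs))
    # average ranks for ties in |d|
    abs_sorted = np.abs(diffs)[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs_sorted[j + 1] == abs_sorted[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[diffs > 0].sum()
    mean_w = ranks.sum() / 2
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2 ** n


class TestComparePaired:
    def test_identical_vectors_not_significant(self):
        res = compare_paired([0.9, 0.95, 1.0, 0.85], [0.9, 0.95, 1.0, 0.85])
        assert res.p_value == 1.0
        assert not res.significant

    def test_forced_signed_rank_small_n(self):
        # constant second sample fails normality -> Wilcoxon branch;
        # differences [1, 2, 3]: exact two-sided p = 2/8
        res = compare_paired([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.test_name == "wilcoxon_signed_rank"
        assert res.p_value == pytest.approx(0.25)

    def test_exact_p_matches_sign_enumeration(self, rng):
        for n in (5, 8, 10, 12):
            a = rng.normal(size=n)
            b = np.zeros(n)  # constant: forces the rank branch
            res = compare_paired(a, b)
            assert res.test_name == "wilcoxon_signed_rank"
            assert res.p_value == pytest.approx(_exact_wilcoxon_p(a),
                                                abs=1e-12)

    def test_paired_t_branch_for_normal_samples(self, rng):
        a = rng.normal(0.0, 1.0, size=30)
        b = a + rng.normal(0.5, 0.3, size=30)
        res = compare_paired(a, b)
        assert res.test_name == "paired_t"
        assert res.normality_p_a > 0.05 and res.normality_p_b > 0.05
        assert res.significant  # shift of ~0.5 sd at n=30

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_paired([1, 2, 3], [1, 2])

    def test_alpha_controls_significance_flag(self):
        res = StatTestResult("paired_t", 0.03, 0.5, 0.5, alpha=0.01)
        assert not res.significant
        res2 = StatTestResult("paired_t", 0.03, 0.5, 0.5, alpha=0.05)
        assert res2.significant


class TestRunExperiment:
    def test_tidy_outputs_and_pairwise_stats(self, small_cohort):
        from imugait.evaluate import run_experiment
        from imugait.models import TrainConfig
        from imugait.io import SensorSelection

        cohort = [r for r in small_cohort]
        metrics, stats = run_experiment(
            cohort,
            selections=[SensorSelection(sensors=("LP", "RP"))],
            architectures=("smCNN-1D", "sCNN-1D"),
            component_modes=("all",),
            n_repeats=3,
            train_cfg=TrainConfig(max_epochs=2, patience=1, seed=0),
            base_seed=1)
        # 1 selection x 1 mode x 2 architectures x 3 repeats
        assert len(metrics) == 6
        assert not metrics["failed"].any()
        assert metrics["accuracy"].between(0, 1).all()
        assert (metrics["selection"] == "LP+RP").all()
        # one paired comparison per metric for the architecture pair
        assert set(stats["metric"]) == {"accuracy", "macro_recall",
                                        "inference_time_s"}
        assert ((stats["arch_a"] == "sCNN-1D")
                & (stats["arch_b"] == "smCNN-1D")).all()
        assert stats["p_value"].between(0, 1).all()


def test_sensor_subset_enumeration():
    subsets = all_sensor_subsets()
    assert len(subsets) == 31  # 2^5 - 1 non-empty subsets
    assert len({s.sensors for s in subsets}) == 31
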