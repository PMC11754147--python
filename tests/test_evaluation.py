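"""Stratified folds, balanced accuracy, repeated CV, majority-vote ensemble."""

import numpy as np
import pytest

from gazescreen.evaluation import (
    balanced_accuracy,
    ensemble_cv,
    evaluate_tasks,
    majority_vote,
    plain_accuracy,
    run_cv,
    stratified_folds,
)


def labels_13_22():
    labels = {f"d{i}": "dyslexic" for i in range(13)}
    labels.update({f"c{i}": "control" for i in range(22)})
    return labels


class OracleClassifier:
    """Returns the true labels (memorises the mapping input -> label)."""

    def __init__(self, truth):
        self.truth = truth

    def fit(self, items, labels):
        pass

    def predict(self, items):
        return [self.truth[i] for i in items]


class FlippingClassifier(OracleClassifier):
    def predict(self, items):
        flip = {"control": "dyslexic", "dyslexic": "control"}
        return [flip[self.truth[i]] for i in items]


class CountingClassifier(OracleClassifier):
    n_fits = 0

    def fit(self, items, labels):
        CountingClassifier.n_fits += 1


class TestStratifiedFolds:
    def test_study_cohort_splits_28_7(self):
        plan = stratified_folds(labels_13_22(), k=5, seed=0)
        for train, test in plan.folds:
            assert len(test) == 7
            assert len(train) == 28

    def test_partition_disjoint_and_exhaustive(self):
        labels = labels_13_22()
        plan = stratified_folds(labels, k=5, seed=3)
        all_test = [s for _, test in plan.folds for s in test]
        assert sorted(all_test) == sorted(labels)

    def test_per_class_counts_within_one(self):
        labels = labels_13_22()
        plan = stratified_folds(labels, k=5, seed=7)
        for cls in ("dyslexic", "control"):
            counts = [sum(labels[s] == cls for s in test) for _, test in plan.folds]
            assert max(counts) - min(counts) <= 1

    def test_balanced_small_cohort_one_each(self):
        labels = {f"d{i}": "dyslexic" for i in range(5)}
        labels.update({f"c{i}": "control" for i in range(5)})
        plan = stratified_folds(labels, k=5, seed=0)
        for _, test in plan.folds:
            assert sorted(labels[s] for s in test) == ["control", "dyslexic"]

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(labels_13_22(), k=1, seed=0)

    def test_seeded_and_reproducible(self):
        a = stratified_folds(labels_13_22(), k=5, seed=5)
        b = stratified_folds(labels_13_22(), k=5, seed=5)
        c = stratified_folds(labels_13_22(), k=5, seed=6)
        assert a.folds == b.folds
        assert a.folds != c.folds


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        truth = ["dyslexic", "control", "control"]
        assert balanced_accuracy(truth, truth) == 100.0

    def test_all_majority_is_50(self):
        truth = ["dyslexic"] * 13 + ["control"] * 22
        pred = ["dyslexic"] * 35
        assert balanced_accuracy(truth, pred) == 50.0

    def test_hand_computed_mixed_case(self):
        # TP 3, FN 1, TN 4, FP 2 -> (0.75 + 0.6667)/2 = 70.83%
        truth = ["dyslexic"] * 4 + ["control"] * 6
        pred = (["dyslexic"] * 3 + ["control"]) + (["dyslexic"] * 2 + ["control"] * 4)
        assert balanced_accuracy(truth, pred) == pytest.approx(70.833333, abs=1e-4)

    def test_swap_invariance(self):
        rng = np.random.default_rng(0)
        truth = ["dyslexic" if v else "control" for v in rng.integers(0, 2, 30)]
        truth[0], truth[1] = "dyslexic", "control"  # both classes present
        pred = ["dyslexic" if v else "control" for v in rng.integers(0, 2, 30)]
        flip = {"dyslexic": "control", "control": "dyslexic"}
        swapped = balanced_accuracy([flip[t] for t in truth], [flip[p] for p in pred],
                                    positive="dyslexic")
        assert balanced_accuracy(truth, pred) == pytest.approx(swapped)

    def test_equals_plain_accuracy_on_balanced_test_set(self):
        rng = np.random.default_rng(1)
        truth = ["dyslexic"] * 10 + ["control"] * 10
        pred = ["dyslexic" if v else "control" for v in rng.integers(0, 2, 20)]
        # with equal class counts the two metrics coincide for any predictions
        assert balanced_accuracy(truth, pred) == pytest.approx(plain_accuracy(truth, pred))

    def test_matches_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        truth = ["dyslexic" if v else "control" for v in rng.integers(0, 2, 50)]
        pred = ["dyslexic" if v else "control" for v in rng.integers(0, 2, 50)]
        ours = balanced_accuracy(truth, pred)
        ref = sklearn.balanced_accuracy_score(truth, pred) * 100.0
        assert ours == pytest.approx(ref)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(["control", "control"], ["control", "dyslexic"])


class TestRunCv:
    def test_50_trainings_for_k5_n10(self):
        labels = labels_13_22()
        CountingClassifier.n_fits = 0
        record = run_cv(lambda: CountingClassifier(labels), {s: s for s in labels}, labels,
                        k=5, n_repeats=10, seed=0)
        assert record.n_trainings == 50
        assert CountingClassifier.n_fits == 50

    def test_oracle_scores_100_sd_0(self):
        labels = labels_13_22()
        record = run_cv(lambda: OracleClassifier(labels), {s: s for s in labels}, labels,
                        k=5, n_repeats=2, seed=0)
        mean, sd = record.summary()
        assert mean == 100.0 and sd == 0.0

    def test_anti_oracle_scores_0(self):
        labels = labels_13_22()
        record = run_cv(lambda: FlippingClassifier(labels), {s: s for s in labels}, labels,
                        k=5, n_repeats=2, seed=0)
        assert record.summary()[0] == 0.0

    def test_each_subject_tested_once_per_repeat(self):
        labels = labels_13_22()
        record = run_cv(lambda: OracleClassifier(labels), {s: s for s in labels}, labels,
                        k=5, n_repeats=3, seed=0)
        for r in range(3):
            tested = [s for run in record.runs if run.repeat == r
                      for s in run.test_subjects]
            assert sorted(tested) == sorted(labels)

    def test_reproducible_run_to_run(self):
        labels = labels_13_22()

        class SeededRandomClassifier:
            def __init__(self):
                self.rng = np.random.default_rng(99)

            def fit(self, items, labels_):
                pass

            def predict(self, items):
                return ["dyslexic" if v else "control"
                        for v in self.rng.integers(0, 2, len(items))]

        kw = dict(k=5, n_repeats=2, seed=4)
        a = run_cv(lambda: SeededRandomClassifier(), {s: s for s in labels}, labels, **kw)
        b = run_cv(lambda: SeededRandomClassifier(), {s: s for s in labels}, labels, **kw)
        assert [r.predictions for r in a.runs] == [r.predictions for r in b.runs]


class TestMajorityVote:
    def test_two_of_three(self):
        assert majority_vote(["dyslexic", "dyslexic", "control"]) == "dyslexic"

    def test_unanimous(self):
        assert majority_vote(["control"] * 3) == "control"

    def test_even_task_count_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(["control", "dyslexic"])


class TestEnsemble:
    def _records(self, classifiers, labels):
        return {
            t: run_cv(factory, {s: s for s in labels}, labels, k=5, n_repeats=2, seed=0)
            for t, factory in classifiers.items()
        }

    def test_all_correct_gives_100(self):
        labels = labels_13_22()
        records = self._records(
            {t: (lambda: OracleClassifier(labels)) for t in "abc"}, labels)
        ens = ensemble_cv(records, labels)
        assert ens.summary() == (100.0, 0.0)

    def test_one_bad_task_absorbed(self):
        labels = labels_13_22()
        records = self._records(
            {"a": lambda: OracleClassifier(labels),
             "b": lambda: OracleClassifier(labels),
             "c": lambda: FlippingClassifier(labels)}, labels)
        assert ensemble_cv(records, labels).summary() == (100.0, 0.0)

    def test_identical_tasks_equal_single_task(self):
        labels = labels_13_22()
        records = self._records(
            {t: (lambda: FlippingClassifier(labels)) for t in "abc"}, labels)
        ens = ensemble_cv(records, labels)
        assert ens.summary() == records["a"].summary()

    def test_misaligned_plans_rejected(self):
        labels = labels_13_22()
        a = run_cv(lambda: OracleClassifier(labels), {s: s for s in labels}, labels,
                   k=5, n_repeats=1, seed=0)
        b = run_cv(lambda: OracleClassifier(labels), {s: s for s in labels}, labels,
                   k=5, n_repeats=1, seed=1)
        with pytest.raises(ValueError):
            ensemble_cv({"a": a, "b": b}, labels)


def test_evaluate_tasks_end_to_end_summary():
    labels = labels_13_22()
    task_inputs = {t: {s: s for s in labels} for t in ("x", "y", "z")}
    result, records = evaluate_tasks(
        lambda: OracleClassifier(labels), task_inputs, labels,
        k=5, n_repeats=2, seed=0)
    assert set(result.per_task) == {"x", "y", "z"}
    assert result.ensemble == (100.0, 0.0)
    assert all(rec.n_trainings == 10 for rec in records.values())
    table = result.format_table()
    assert "ensemble" in table and "100.00" in table
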