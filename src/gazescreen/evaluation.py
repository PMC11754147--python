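"""Stratified repeated k-fold cross-validation, balanced accuracy, and
majority-vote ensembling across reading tasks.

Subjects (not individual recordings) are the cross-validation unit: one
FoldPlan partitions the participant set, and the same partition is applied
to every reading task so that per-task predictions for a subject can later
be combined by majority vote.  Because the cohort is class-imbalanced,
performance is reported as balanced accuracy — the mean of recall (true
positive rate over the dyslexic class) and specificity (true negative rate)
— expressed in percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np

POSITIVE_CLASS = "dyslexic"


@dataclass
class FoldPlan:
    """k train/test splits of the subject set for one repeat."""

    folds: list[tuple[tuple[str, ...], tuple[str, ...]]]
    seed: int
    k: int

    def test_partition(self) -> tuple[tuple[str, ...], ...]:
        return tuple(test for _, test in self.folds)


def stratified_folds(
    labels: Mapping[str, str], k: int, seed: int
) -> FoldPlan:
    """Partition subjects into k folds, stratified by class.

    Each class is shuffled with the given seed and dealt round-robin into
    the folds; the deal of the next class starts at the fold after the one
    where the previous class stopped, so per-class remainders land on
    different folds and fold sizes stay as equal as the totals allow (for
    13 + 22 subjects and k = 5 every test fold has exactly 7 subjects).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    subjects = list(labels)
    if k > len(subjects):
        raise ValueError("k cannot exceed the number of subjects")
    rng = np.random.default_rng(seed)
    fold_members: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for cls in sorted(set(labels.values())):
        members = [s for s in subjects if labels[s] == cls]
        order = rng.permutation(len(members))
        for i, idx in enumerate(order):
            fold_members[(offset + i) % k].append(members[idx])
        offset = (offset + len(members)) % k
    folds = []
    for f in range(k):
        test = tuple(fold_members[f])
        train = tuple(s for g in range(k) if g != f for s in fold_members[g])
        folds.append((train, test))
    return FoldPlan(folds=folds, seed=seed, k=k)


def balanced_accuracy(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive: str = POSITIVE_CLASS,
) -> float:
    """(recall + specificity) / 2 in percent.

    Recall is the fraction of positive-class subjects predicted positive;
    specificity the fraction of the rest predicted non-positive.  Undefined
    (raises) when the true labels contain only one class.
    """
    if len(true_labels) != len(predicted_labels) or not true_labels:
        raise ValueError("label lists must be non-empty and of equal length")
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    pos = t == positive
    if pos.all() or not pos.any():
        raise ValueError("balanced accuracy undefined with a single true class")
    recall = float((p[pos] == positive).mean())
    specificity = float((p[~pos] != positive).mean())
    return (recall + specificity) / 2.0 * 100.0


def plain_accuracy(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> float:
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    return float((t == p).mean()) * 100.0


def majority_vote(votes: Sequence[str]) -> str:
    """Strict-majority class among an odd number of per-task votes."""
    if len(votes) % 2 == 0:
        raise ValueError(
            "majority vote requires an odd number of tasks (ties possible otherwise)"
        )
    classes = sorted(set(votes))
    counts = {c: sum(v == c for v in votes) for c in classes}
    return max(classes, key=lambda c: counts[c])


@dataclass
class RunResult:
    """Predictions and scores of one (repeat, fold) training run."""

    repeat: int
    fold: int
    test_subjects: tuple[str, ...]
    predictions: dict[str, str]
    balanced_accuracy_pct: float
    accuracy_pct: float


@dataclass
class CvRecord:
    """All n_repeats x k runs of one classifier on one task."""

    runs: list[RunResult]
    k: int
    n_repeats: int
    seed: int

    @property
    def n_trainings(self) -> int:
        return len(self.runs)

    def summary(self) -> tuple[float, float]:
        """Mean and population SD of balanced accuracy over all runs."""
        vals = np.array([r.balanced_accuracy_pct for r in self.runs])
        return float(vals.mean()), float(vals.std(ddof=0))

    def accuracy_summary(self) -> tuple[float, float]:
        vals = np.array([r.accuracy_pct for r in self.runs])
        return float(vals.mean()), float(vals.std(ddof=0))


def run_cv(
    classifier_factory: Callable[[], Any],
    inputs: Mapping[str, Any],
    labels: Mapping[str, str],
    k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> CvRecord:
    """Stratified k-fold CV repeated n times; one fresh classifier per run.

    ``inputs`` maps each subject to whatever the classifier consumes (a
    Recording, a FixImage, ...); the classifier must expose ``fit(items,
    labels)`` and ``predict(items)``.  Folds are re-drawn per repeat with a
    derived seed (repeat r uses ``seed + r``), so the reported spread also
    covers fold-composition variability.
    """
    if set(inputs) != set(labels):
        raise ValueError("inputs and labels must cover the same subjects")
    runs: list[RunResult] = []
    for r in range(n_repeats):
        plan = stratified_folds(labels, k, seed + r)
        for f, (train, test) in enumerate(plan.folds):
            test_classes = {labels[s] for s in test}
            if len(test_classes) < 2:
                raise RuntimeError(
                    f"repeat {r} fold {f} has a single-class test set; "
                    "stratification should prevent this"
                )
            clf = classifier_factory()
            clf.fit([inputs[s] for s in train], [labels[s] for s in train])
            preds = clf.predict([inputs[s] for s in test])
            truth = [labels[s] for s in test]
            runs.append(
                RunResult(
                    repeat=r,
                    fold=f,
                    test_subjects=tuple(test),
                    predictions=dict(zip(test, preds)),
                    balanced_accuracy_pct=balanced_accuracy(truth, preds),
                    accuracy_pct=plain_accuracy(truth, preds),
                )
            )
    return CvRecord(runs=runs, k=k, n_repeats=n_repeats, seed=seed)


def ensemble_cv(
    records: Mapping[str, CvRecord],
    labels: Mapping[str, str],
    n_vote_tasks: int | None = None,
    seed: int | None = None,
) -> CvRecord:
    """Majority-vote ensemble over per-task CV records with aligned folds.

    For every (repeat, fold) run each test subject's final label is the
    majority vote of that subject's per-task predictions; balanced accuracy
    is then computed on the ensembled labels.  ``n_vote_tasks`` optionally
    votes over a seeded random subset of tasks per run (odd, to preclude
    ties).
    """
    tasks = sorted(records)
    if not tasks:
        raise ValueError("no per-task records supplied")
    ref = records[tasks[0]]
    for t in tasks[1:]:
        rec = records[t]
        if (rec.k, rec.n_repeats, rec.seed) != (ref.k, ref.n_repeats, ref.seed):
            raise ValueError("per-task records use different CV configurations")
        for a, b in zip(ref.runs, rec.runs):
            if a.test_subjects != b.test_subjects:
                raise ValueError("fold plans are misaligned across tasks")
    rng = np.random.default_rng(seed) if n_vote_tasks is not None else None
    runs: list[RunResult] = []
    for i, ref_run in enumerate(ref.runs):
        voting_tasks = tasks
        if n_vote_tasks is not None:
            idx = rng.choice(len(tasks), size=n_vote_tasks, replace=False)
            voting_tasks = [tasks[j] for j in sorted(idx)]
        preds = {
            s: majority_vote([records[t].runs[i].predictions[s] for t in voting_tasks])
            for s in ref_run.test_subjects
        }
        truth = [labels[s] for s in ref_run.test_subjects]
        voted = [preds[s] for s in ref_run.test_subjects]
        runs.append(
            RunResult(
                repeat=ref_run.repeat,
                fold=ref_run.fold,
                test_subjects=ref_run.test_subjects,
                predictions=preds,
                balanced_accuracy_pct=balanced_accuracy(truth, voted),
                accuracy_pct=plain_accuracy(truth, voted),
            )
        )
    return CvRecord(runs=runs, k=ref.k, n_repeats=ref.n_repeats, seed=ref.seed)


@dataclass
class EvalResult:
    """Per-task and ensemble balanced accuracy (mean +/- SD, percent)."""

    per_task: dict[str, tuple[float, float]]
    ensemble: tuple[float, float] | None
    per_task_accuracy: dict[str, tuple[float, float]] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_task": {
                t: {"mean_pct": m, "sd_pct": s} for t, (m, s) in self.per_task.items()
            },
            "per_task_plain_accuracy": {
                t: {"mean_pct": m, "sd_pct": s}
                for t, (m, s) in self.per_task_accuracy.items()
            },
            "ensemble": None
            if self.ensemble is None
            else {"mean_pct": self.ensemble[0], "sd_pct": self.ensemble[1]},
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def format_table(self) -> str:
        """Aligned text table: one column per task plus the ensemble."""
        cols = list(self.per_task) + (["ensemble"] if self.ensemble else [])
        cells = {**self.per_task}
        if self.ensemble:
            cells["ensemble"] = self.ensemble
        header = "  ".join(f"{c:>22}" for c in cols)
        row = "  ".join(
            f"{cells[c][0]:>14.2f} +/- {cells[c][1]:5.2f}" for c in cols
        )
        return header + "\n" + row


def evaluate_tasks(
    classifier_factory: Callable[[], Any],
    task_inputs: Mapping[str, Mapping[str, Any]],
    labels: Mapping[str, str],
    k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    ensemble: bool = True,
) -> tuple[EvalResult, dict[str, CvRecord]]:
    """Run per-task CV and (optionally) the cross-task majority-vote ensemble."""
    records = {
        task: run_cv(classifier_factory, inputs, labels, k, n_repeats, seed)
        for task, inputs in task_inputs.items()
    }
    ens = ensemble_cv(records, labels).summary() if ensemble and len(records) > 1 else None
    result = EvalResult(
        per_task={t: rec.summary() for t, rec in records.items()},
        ensemble=ens,
        per_task_accuracy={t: rec.accuracy_summary() for t, rec in records.items()},
        provenance={"k": k, "n_repeats": n_repeats, "seed": seed},
    )
    return result, records
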