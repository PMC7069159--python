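"""Balanced-undersampling evaluation protocol for imbalanced cohorts.

Chronic-condition classes are heavily imbalanced (tens of thousands of
hypertensive patients against a few hundred with multiple dominant chronic
conditions), so both training and test sets are balanced by undersampling:
with m the minority-class size and train fraction f, each class contributes
⌊f·m⌋ training and ⌊(1−f)·m⌋ test samples, drawn without replacement and
disjointly.  The protocol repeats over many random trials (50 by default)
and reports mean and standard deviation of accuracy (%), macro-F1, and the
row-percentage confusion matrix.

Because test sets are balanced, overall accuracy equals the unweighted mean
of the confusion-matrix diagonal — asserted per trial as a sanity identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .tree import ClassificationTree, build_tree, predict

__all__ = [
    "TrialSplit",
    "EvaluationReport",
    "trial_split",
    "confusion_matrix_percent",
    "macro_f1",
    "run_trials",
]


@dataclass
class TrialSplit:
    train: Cohort
    test: Cohort
    seed: int


@dataclass
class EvaluationReport:
    classes: list
    n_trials: int
    accuracies: np.ndarray  # per-trial, in percent
    f1_scores: np.ndarray  # per-trial macro-F1 in [0, 1]
    confusions: np.ndarray  # n_trials x C x C row-percentage matrices

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracies.std())

    @property
    def mean_f1(self) -> float:
        return float(self.f1_scores.mean())

    @property
    def std_f1(self) -> float:
        return float(self.f1_scores.std())

    @property
    def mean_confusion(self) -> np.ndarray:
        return self.confusions.mean(axis=0)

    @property
    def std_confusion(self) -> np.ndarray:
        return self.confusions.std(axis=0)

    def summary(self) -> str:
        return (f"{self.n_trials} trials: accuracy {self.mean_accuracy:.2f}% "
                f"({self.std_accuracy:.2f}), macro-F1 {self.mean_f1:.4f} "
                f"({self.std_f1:.4f})")

    def to_json(self) -> str:
        return json.dumps({
            "classes": [str(c) for c in self.classes],
            "n_trials": self.n_trials,
            "accuracies": self.accuracies.tolist(),
            "f1_scores": self.f1_scores.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "mean_f1": self.mean_f1,
            "std_f1": self.std_f1,
            "mean_confusion": self.mean_confusion.tolist(),
            "std_confusion": self.std_confusion.tolist(),
        }, indent=2, sort_keys=True)

    def trials_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(self.n_trials),
            "accuracy_percent": self.accuracies,
            "macro_f1": self.f1_scores,
        })

    def mean_confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_confusion, index=self.classes, columns=self.classes)


def trial_split(cohort: Cohort, train_fraction: float = 0.8, seed: int = 0) -> TrialSplit:
    """One balanced undersampled train/test split.

    With m the minority-class size, every class contributes ⌊f·m⌋ training
    samples and ⌊(1−f)·m⌋ test samples, drawn uniformly without replacement
    and disjoint from the training draw.  Reproducible from ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    classes = cohort.classes
    sizes = {c: int((cohort.y == c).sum()) for c in classes}
    small = [c for c, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    m = min(sizes.values())
    # epsilon guards the floor against binary-fraction round-off, e.g. (1-0.8)*10
    n_train = int(np.floor(train_fraction * m + 1e-9))
    n_test = int(np.floor((1 - train_fraction) * m + 1e-9))
    if n_train < 1 or n_test < 1:
        raise ValueError("minority class too small for the requested fractions")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in classes:
        members = np.flatnonzero(cohort.y == c)
        picked = rng.choice(members, size=n_train + n_test, replace=False)
        train_idx.append(picked[:n_train])
        test_idx.append(picked[n_train:])
    return TrialSplit(
        train=cohort.select_samples(np.concatenate(train_idx)),
        test=cohort.select_samples(np.concatenate(test_idx)),
        seed=seed,
    )


def confusion_matrix_percent(true, predicted, classes) -> np.ndarray:
    """C×C row-percentage confusion matrix: entry (i,j) is the percentage of
    class-i samples predicted as class j; every non-empty row sums to 100."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if len(true) != len(predicted):
        raise ValueError("true/predicted length mismatch")
    C = len(classes)
    M = np.zeros((C, C))
    for i, ci in enumerate(classes):
        mask = true == ci
        n = int(mask.sum())
        if n == 0:
            continue  # empty true class: row of zeros
        for j, cj in enumerate(classes):
            M[i, j] = 100.0 * int((predicted[mask] == cj).sum()) / n
    return M


def macro_f1(true, predicted) -> float:
    """Unweighted mean over classes of the one-vs-rest F1 = 2PR/(P+R).

    A class with zero precision and recall contributes 0.  Classes are the
    union of labels observed in ``true`` and ``predicted``.
    """
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if len(true) != len(predicted):
        raise ValueError("true/predicted length mismatch")
    classes = sorted(set(true.tolist()) | set(predicted.tolist()))
    f1s = []
    for c in classes:
        tp = int(((true == c) & (predicted == c)).sum())
        fp = int(((true != c) & (predicted == c)).sum())
        fn = int(((true == c) & (predicted != c)).sum())
        if tp == 0:
            f1s.append(0.0)  # P + R = 0 (or undefined): F1 defined as 0
            continue
        p = tp / (tp + fp)
        r = tp / (tp + fn)
        f1s.append(2 * p * r / (p + r))
    return float(np.mean(f1s))


def run_trials(
    cohort: Cohort,
    n_trials: int = 50,
    base_seed: int = 0,
    train_fraction: float = 0.8,
    tree: ClassificationTree | None = None,
    builder_params: dict | None = None,
    permute_labels: bool = False,
) -> EvaluationReport:
    """Repeated balanced-undersampling evaluation.

    Each trial t uses seed ``base_seed + t`` to draw a balanced split.  With
    ``tree`` given, the fixed tree (e.g. one designed interactively) is only
    evaluated on the trial's balanced test set; otherwise a tree is rebuilt
    on each trial's balanced training set with the automatic selector and
    ``builder_params``.  ``permute_labels`` shuffles the cohort's labels
    once (seeded) before the trials — a chance-level control.
    """
    if permute_labels:
        rng = np.random.default_rng(base_seed)
        cohort = Cohort(cohort.X, rng.permutation(cohort.y), cohort.schema,
                        cohort.sample_ids)
    classes = cohort.classes
    params = builder_params or {}
    accs, f1s, mats = [], [], []
    for t in range(n_trials):
        try:
            split = trial_split(cohort, train_fraction, seed=base_seed + t)
            model = tree if tree is not None else build_tree(split.train, **params)
            pred = predict(model, split.test.X)
        except ValueError as e:
            raise ValueError(f"trial {t} failed: {e}") from e
        true = split.test.y
        acc = 100.0 * float((pred == true).mean())
        M = confusion_matrix_percent(true, pred, classes)
        # balanced test set: accuracy must equal the diagonal mean exactly
        assert abs(acc - float(np.diag(M).mean())) < 1e-9
        accs.append(acc)
        f1s.append(macro_f1(true, pred))
        mats.append(M)
    return EvaluationReport(
        classes=classes,
        n_trials=n_trials,
        accuracies=np.asarray(accs),
        f1_scores=np.asarray(f1s),
        confusions=np.asarray(mats),
    )
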