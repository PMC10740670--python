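"""Validation protocol: per-fish K-fold splits, confusion matrices, and
permutation-test significance thresholds.

Folds are assigned by fish, stratified by condition, so all segments of one
animal share a fold — otherwise the classifier could key on the phenotype
of a particular individual rather than on the treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import PredictionRecord
from .trajectory import ValidationError

__all__ = [
    "FoldAssignment",
    "ConfusionMatrix",
    "PermutationNull",
    "kfold_split",
    "confusion_matrix",
    "accuracy",
    "permutation_threshold",
]


@dataclass
class FoldAssignment:
    k: int
    fold_of_fish: dict  # fish_id -> fold index

    def fish_in_fold(self, fold: int) -> list:
        return [f for f, fo in self.fold_of_fish.items() if fo == fold]


@dataclass
class ConfusionMatrix:
    """Raw prediction counts: rows = true (test) class, columns = predicted."""

    train_classes: list  # column labels (predicted)
    test_classes: list  # row labels (true)
    counts: np.ndarray  # (M, N) int

    def row_normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValidationError("confusion matrix has an empty row")
        return self.counts / sums

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[getattr(c, "name", str(c)) for c in self.test_classes],
            columns=[getattr(c, "name", str(c)) for c in self.train_classes],
        )


@dataclass
class PermutationNull:
    n_permutations: int
    statistic_samples: np.ndarray
    alpha: float
    threshold: float


def kfold_split(manifest: pd.DataFrame, k: int, seed: int = 0) -> FoldAssignment:
    """Assign each fish to one of ``k`` folds, stratified by condition.

    ``manifest`` needs columns ``fish_id`` and ``label`` (one row per fish;
    duplicate fish rows are collapsed).  Within every condition the fish are
    shuffled and dealt round-robin, so per-condition fold sizes differ by at
    most one.  Every condition must contribute at least ``k`` fish.
    """
    fish = manifest[["fish_id", "label"]].drop_duplicates("fish_id")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([seed])))
    fold_of_fish: dict = {}
    for label, group in sorted(fish.groupby("label"), key=lambda kv: str(kv[0])):
        ids = sorted(group["fish_id"])
        if len(ids) < k:
            raise ValidationError(
                f"condition {label!r} has {len(ids)} fish, fewer than k={k}"
            )
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            fold_of_fish[ids[idx]] = pos % k
    return FoldAssignment(k=k, fold_of_fish=fold_of_fish)


def confusion_matrix(records: list[PredictionRecord], train_classes,
                     test_classes) -> ConfusionMatrix:
    """Tally prediction counts over all records (aggregated across folds)."""
    train_classes = list(train_classes)
    test_classes = list(test_classes)
    col = {c: j for j, c in enumerate(train_classes)}
    row = {c: i for i, c in enumerate(test_classes)}
    counts = np.zeros((len(test_classes), len(train_classes)), dtype=np.int64)
    for r in records:
        if r.true_label not in row:
            raise ValidationError(f"unknown true label {r.true_label}")
        if r.predicted_label not in col:
            raise ValidationError(f"unknown predicted label {r.predicted_label}")
        counts[row[r.true_label], col[r.predicted_label]] += 1
    return ConfusionMatrix(train_classes=train_classes, test_classes=test_classes,
                           counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: matching-label counts over the total."""
    total = cm.counts.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    correct = sum(
        cm.counts[i, j]
        for i, t in enumerate(cm.test_classes)
        for j, p in enumerate(cm.train_classes)
        if t == p
    )
    return float(correct / total)


def _stat_accuracy(true_idx: np.ndarray, pred_idx: np.ndarray) -> float:
    return float((true_idx == pred_idx).mean())


def permutation_threshold(
    records: list[PredictionRecord],
    statistic: str = "accuracy",
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    *,
    predicted_class=None,
    true_class=None,
) -> PermutationNull:
    """Empirical null of a prediction statistic under shuffled true labels.

    ``statistic='accuracy'``: overall fraction correct.
    ``statistic='class_fraction'``: among records whose (shuffled) true label
    is ``true_class``, the fraction predicted as ``predicted_class`` — the
    per-bin baseline used by the time-resolved analysis.
    The threshold is the empirical (1 − alpha) quantile of the null samples.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if not records:
        raise ValidationError("no records")
    true_labels = [r.true_label for r in records]
    pred_labels = [r.predicted_label for r in records]
    classes = sorted(set(true_labels) | set(pred_labels))
    cindex = {c: i for i, c in enumerate(classes)}
    true_idx = np.array([cindex[t] for t in true_labels])
    pred_idx = np.array([cindex[p] for p in pred_labels])
    entropy = list(seed) if isinstance(seed, (list, tuple)) else [seed]
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(entropy)))

    if statistic == "accuracy":
        def stat(t):
            return _stat_accuracy(t, pred_idx)
    elif statistic == "class_fraction":
        if predicted_class is None or true_class is None:
            raise ValidationError(
                "class_fraction requires predicted_class and true_class")
        pc = cindex.get(predicted_class)
        tc = cindex.get(true_class)
        if pc is None or tc is None:
            raise ValidationError("class not present among records")

        def stat(t):
            mask = t == tc
            n = mask.sum()
            return float((pred_idx[mask] == pc).mean()) if n else 0.0
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")

    samples = np.empty(n_permutations)
    for i in range(n_permutations):
        samples[i] = stat(rng.permutation(true_idx))
    threshold = float(np.quantile(samples, 1.0 - alpha))
    return PermutationNull(
        n_permutations=n_permutations,
        statistic_samples=samples,
        alpha=alpha,
        threshold=threshold,
    )
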