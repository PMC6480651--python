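"""Performance machinery: confusion bookkeeping, Q(n), TPR/FPR, ROC/AUC,
reliability-threshold curves, and stratified cross-validation.

Accounting is per observed annotation, not per protein: a protein with two
observed compartments contributes mass 1 to each of its two observed
columns, so column sums of the confusion matrix equal per-class annotation
counts and their total can exceed the protein count. Q(n) is the percentage
of observed annotations recovered on the diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io_formats import AnnotationDB
from .predictor import Prediction
from .vocabulary import COMPARTMENTS, NONE_LABEL

__all__ = [
    "ClassCounts",
    "ConfusionMatrix",
    "per_class_counts",
    "build_confusion",
    "q_n",
    "tpr",
    "fpr",
    "roc_auc",
    "ri_curve",
    "stratified_kfold",
    "round_half_away",
    "majority_class_baseline",
    "frequency_squared_baseline",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(np.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ClassCounts:
    """Per-label TP/FP/FN/TN over an evaluation set (per-protein basis)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ConfusionMatrix:
    """(13 predicted + "None") x 13 observed mass matrix.

    Each observed annotation contributes total mass exactly 1 to its column,
    so ``observed_totals`` are the per-class annotation counts.
    """

    counts: pd.DataFrame  # rows: labels + NONE_LABEL; columns: labels

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("confusion matrix has negative mass")

    @property
    def labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def observed_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def predicted_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def diagonal(self) -> pd.Series:
        return pd.Series({c: self.counts.at[c, c] for c in self.counts.columns})

    @classmethod
    def from_tsv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        return cls(df.astype(float))

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def per_class_counts(
    observed: dict[str, frozenset[str]],
    predictions: Iterable[Prediction],
    labels: Sequence[str] = COMPARTMENTS,
) -> dict[str, ClassCounts]:
    """TP/FP/FN/TN per label, one unit per evaluated protein."""
    counts = {l: [0, 0, 0, 0] for l in labels}  # tp, fp, fn, tn
    for pred in predictions:
        obs = observed[pred.protein]
        for l in labels:
            in_pred, in_obs = l in pred.labels, l in obs
            if in_pred and in_obs:
                counts[l][0] += 1
            elif in_pred:
                counts[l][1] += 1
            elif in_obs:
                counts[l][2] += 1
            else:
                counts[l][3] += 1
    return {l: ClassCounts(*v) for l, v in counts.items()}


def build_confusion(
    observed: AnnotationDB | dict[str, frozenset[str]],
    predictions: Iterable[Prediction],
    attribution: str = "top-score",
    labels: Sequence[str] = COMPARTMENTS,
) -> ConfusionMatrix:
    """Distribute each observed annotation over the predicted rows.

    For each protein and each observed label c: a correct prediction puts
    mass 1 at (c, c); an empty prediction puts it in the "None" row; a miss
    goes either entirely to the top-scoring predicted label (``top-score``;
    lexicographic tie-break when no scores are attached, e.g. HB
    predictions) or spread as 1/|P| over the predicted rows (``fractional``).
    """
    if attribution not in ("top-score", "fractional"):
        raise ValueError(f"unknown attribution {attribution!r}")
    obs_map = observed.labels if isinstance(observed, AnnotationDB) else observed
    rows = list(labels) + [NONE_LABEL]
    M = pd.DataFrame(0.0, index=rows, columns=list(labels))
    for pred in predictions:
        if pred.protein not in obs_map:
            raise KeyError(f"prediction for unannotated protein {pred.protein!r}")
        for c in obs_map[pred.protein]:
            if c in pred.labels:
                M.at[c, c] += 1.0
            elif not pred.labels:
                M.at[NONE_LABEL, c] += 1.0
            elif attribution == "fractional":
                share = 1.0 / len(pred.labels)
                for p in pred.labels:
                    M.at[p, c] += share
            else:
                if pred.scores:
                    top = max(pred.labels, key=lambda l: (pred.scores.get(l, -np.inf), l))
                else:
                    top = min(pred.labels)
                M.at[top, c] += 1.0
    return ConfusionMatrix(M)


def q_n(confusion: ConfusionMatrix) -> float:
    """Overall accuracy: 100 * (diagonal mass) / (total observed annotations)."""
    total = float(confusion.observed_totals.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(confusion.diagonal().sum()) / total


def tpr(counts: ClassCounts) -> float:
    """True-positive rate, percent: 100*TP/(TP+FN); NaN when undefined."""
    denom = counts.tp + counts.fn
    if denom == 0:
        warnings.warn("TPR undefined: TP+FN == 0")
        return float("nan")
    return 100.0 * counts.tp / denom


def fpr(counts: ClassCounts) -> float:
    """False-positive rate, percent: 100 - 100*TN/(TN+FP); NaN when undefined."""
    denom = counts.tn + counts.fp
    if denom == 0:
        warnings.warn("FPR undefined: TN+FP == 0")
        return float("nan")
    return 100.0 - 100.0 * counts.tn / denom


def roc_auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Area under the ROC curve (trapezoid over thresholds, ties averaged).

    Equivalent to the Mann-Whitney rank-sum formulation:
    (concordant pairs + half ties) / (positives x negatives).
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def ri_curve(
    predictions: list[Prediction],
    observed: AnnotationDB | dict[str, frozenset[str]],
    bin_width: int = 20,
    attribution: str = "top-score",
) -> list[tuple[int, float, float]]:
    """Cumulative (RI threshold, coverage %, accuracy %) at bin_width steps.

    At threshold t, accuracy is Q(n) over predictions with RI >= t and
    coverage is the percentage of proteins retained; threshold 0 gives
    coverage 100 and the overall Q(n).
    """
    points = []
    n_all = len(predictions)
    for t in range(0, 101, bin_width):
        kept = [p for p in predictions if p.ri >= t]
        coverage = 100.0 * len(kept) / n_all if n_all else 0.0
        if kept:
            acc = q_n(build_confusion(observed, kept, attribution))
        else:
            acc = float("nan")
        points.append((t, coverage, acc))
    return points


def stratified_kfold(
    ids: Sequence[str],
    labels: Sequence[str],
    k: int = 5,
    seed: int = 0,
) -> list[list[str]]:
    """Partition ids into k folds with per-class counts within +-1 of equal.

    ``labels`` gives one stratification key per id (for multi-label data,
    callers typically stratify on each protein's rarest label). Within each
    class, shuffled members are dealt round-robin, with the starting fold
    rotating between classes to balance fold sizes.
    """
    if len(ids) != len(labels):
        raise ValueError("ids and labels must align")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of samples {len(ids)}")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for pid, lab in zip(ids, labels):
        by_class.setdefault(lab, []).append(pid)
    folds: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for lab in sorted(by_class):
        members = sorted(by_class[lab])
        rng.shuffle(members)
        for i, pid in enumerate(members):
            folds[(offset + i) % k].append(pid)
        offset = (offset + len(members)) % k
    return folds


def majority_class_baseline(observed_totals: pd.Series) -> float:
    """Q(n) of always predicting the largest class, percent."""
    return 100.0 * float(observed_totals.max()) / float(observed_totals.sum())


def frequency_squared_baseline(observed_totals: pd.Series) -> float:
    """Q(n) of drawing labels from the observed class frequencies, percent."""
    f = observed_totals / observed_totals.sum()
    return 100.0 * float((f**2).sum())
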