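"""Compartment composition spectra, prediction-bias correction, spectrum
distances and the agreement score for homologous protein pairs.

A *spectrum* is the composition of predicted compartments over a protein
set: the fraction of label assignments falling on each of the 13 classes.
Classifier bias (over-calling some compartments) can be corrected with the
confusion matrix of a labeled development set: if ``M[i, j]`` is the
probability of predicting j (including "no call") given observed class i,
the observed prediction counts q satisfy q = M' p, and the underlying class
distribution p is recovered by non-negative least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import nnls

from .evaluation import ConfusionMatrix
from .predictor import Prediction
from .vocabulary import COMPARTMENTS

__all__ = [
    "Spectrum",
    "spectrum",
    "predicted_label_counts",
    "bias_correct",
    "spectrum_distance",
    "agreement",
    "agreement_cdf",
]


@dataclass
class Spectrum:
    """Non-negative 13-vector of label-assignment fractions summing to 1."""

    fractions: np.ndarray
    labels: tuple[str, ...] = COMPARTMENTS
    n: int = 0  # number of underlying label assignments

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.labels),):
            raise ValueError("spectrum length must match label vocabulary")
        if np.any(self.fractions < 0):
            raise ValueError("spectrum fractions must be >= 0")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"spectrum must sum to 1, got {self.fractions.sum()!r}")

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.fractions


def _label_sets(predictions: Iterable[Prediction | frozenset[str] | set[str]]):
    for p in predictions:
        yield p.labels if isinstance(p, Prediction) else frozenset(p)


def predicted_label_counts(
    predictions: Iterable[Prediction | frozenset[str]],
    labels: Sequence[str] = COMPARTMENTS,
) -> np.ndarray:
    counts = np.zeros(len(labels))
    index = {l: i for i, l in enumerate(labels)}
    for ls in _label_sets(predictions):
        for l in ls:
            counts[index[l]] += 1
    return counts


def spectrum(
    predictions: Iterable[Prediction | frozenset[str]],
    labels: Sequence[str] = COMPARTMENTS,
) -> Spectrum:
    """Composition of predicted compartments; empty predictions are excluded."""
    counts = predicted_label_counts(predictions, labels)
    total = counts.sum()
    if total == 0:
        raise ValueError("all predictions empty; spectrum undefined")
    return Spectrum(counts / total, tuple(labels), n=int(total))


def bias_correct(
    predicted_counts: np.ndarray,
    confusion: ConfusionMatrix,
    ridge: float = 1e-6,
    cond_threshold: float = 1e10,
) -> Spectrum:
    """Estimate the true class distribution behind biased prediction counts.

    ``confusion`` is the development-set confusion matrix (rows: 13
    predicted classes + "None", columns: 13 observed classes). Its
    column-normalized transpose M gives P(predicted outcome | observed
    class); the true distribution p solves q = M' p. ``predicted_counts``
    may have 13 entries (per-class counts only) or 14 (with the "None"
    outcome appended). Solved as unnormalized NNLS followed by
    normalization, which recovers p exactly in the noiseless forward-model
    case; an ill-conditioned system falls back to a ridge-regularized solve
    with a warning.
    """
    q = np.asarray(predicted_counts, dtype=float)
    obs_totals = confusion.observed_totals.to_numpy()
    if np.any(obs_totals <= 0):
        raise ValueError("development confusion must cover all observed classes")
    # M: observed class (13) x predicted outcome (14)
    M = (confusion.counts.to_numpy() / obs_totals).T
    n_classes = M.shape[0]
    if q.shape == (n_classes,):
        A = M[:, :n_classes].T
    elif q.shape == (M.shape[1],):
        A = M.T
    else:
        raise ValueError(f"predicted_counts must have {n_classes} or {M.shape[1]} entries")
    if np.linalg.cond(A) > cond_threshold:
        warnings.warn("ill-conditioned development confusion; using ridge-regularized solve")
        x = np.linalg.solve(A.T @ A + ridge * np.eye(n_classes), A.T @ q)
        x = np.clip(x, 0.0, None)
    else:
        x, _ = nnls(A, q)
    if x.sum() == 0:
        raise ValueError("bias correction produced an all-zero distribution")
    return Spectrum(x / x.sum(), tuple(confusion.labels), n=int(round(q.sum())))


def spectrum_distance(
    a: Spectrum,
    b: Spectrum,
    bootstrap: int = 0,
    seed: int | None = None,
    assignments_a: Sequence[frozenset[str]] | None = None,
    assignments_b: Sequence[frozenset[str]] | None = None,
) -> tuple[float, float]:
    """Euclidean distance between two spectra on the percent scale.

    With ``bootstrap > 0`` and the per-protein label sets of both
    collections supplied, proteins are resampled with replacement within
    each set and the standard error of the distance is the standard
    deviation over replicates; otherwise the second element is NaN.
    """
    if a.labels != b.labels:
        raise ValueError("spectra must share the same label vocabulary")
    dist = float(np.linalg.norm(a.percent - b.percent))
    if bootstrap <= 0:
        return dist, float("nan")
    if assignments_a is None or assignments_b is None:
        raise ValueError("bootstrap requires the underlying label sets of both collections")
    rng = np.random.default_rng(seed)
    la = [s for s in assignments_a if s]
    lb = [s for s in assignments_b if s]
    reps = np.empty(bootstrap)
    for r in range(bootstrap):
        sa = spectrum([la[i] for i in rng.integers(0, len(la), len(la))], a.labels)
        sb = spectrum([lb[i] for i in rng.integers(0, len(lb), len(lb))], b.labels)
        reps[r] = np.linalg.norm(sa.percent - sb.percent)
    return dist, float(reps.std(ddof=1))


def agreement(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Fraction of agreement between two predicted label sets.

    With n = max(|A|, |B|), the score is the fraction of the larger set's
    labels found in the other set, i.e. |A intersect B| / n. Symmetric,
    bounded in [0, 1], and 1 iff the sets are identical.
    """
    if not a or not b:
        raise ValueError("agreement undefined for empty label sets")
    return len(set(a) & set(b)) / max(len(a), len(b))


def agreement_cdf(scores: Sequence[float], grid: Sequence[float] | None = None):
    """Cumulative distribution of agreement scores (fraction >= threshold)."""
    s = np.asarray(scores, dtype=float)
    if grid is None:
        grid = np.round(np.arange(0.0, 1.01, 0.1), 10)
    return [(float(t), float(np.mean(s >= t))) for t in grid]
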