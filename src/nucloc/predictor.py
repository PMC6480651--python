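"""The combined prediction protocol and the SVM reliability index.

The protocol is strictly either/or: if an annotated homolog passes the
E-value filter, its label set is transferred (source ``HB``); otherwise the
one-vs-rest SVM battery decides (source ``ML``), switching on every label
with a positive decision value. If the SVMs fire for no label, the outcome
is "None" (source ``NONE``).

The reliability index for ML predictions rescales the raw decision value of
the top label against the largest raw score that label reached on the
training positives: ``RI = round(raw * 100 / max_raw)``, clamped to [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .homology_inference import EVALUE_SUBNUCLEAR, infer, ri_hb
from .io_formats import AnnotationDB, HomologyHit, Profile
from .profile_kernel import FeatureVector, feature_map
from .svm_battery import TrainedClassifier, decision_values, predict_labels

__all__ = ["Prediction", "RIContext", "build_ri_context", "ri_svm", "predict", "predict_batch"]


@dataclass(frozen=True)
class Prediction:
    """Predicted label set with provenance and reliability.

    ``source`` is ``HB`` (homology transfer), ``ML`` (SVM battery) or
    ``NONE`` (no label fired); ``labels`` is empty iff source is ``NONE``.
    ``scores`` keeps the raw SVM decision values when the ML route ran.
    """

    protein: str
    labels: frozenset[str]
    ri: int
    source: str
    scores: dict[str, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.source not in ("HB", "ML", "NONE"):
            raise ValueError(f"unknown source {self.source!r}")
        if (self.source == "NONE") != (len(self.labels) == 0):
            raise ValueError("source NONE iff label set empty")
        if not 0 <= self.ri <= 100:
            raise ValueError(f"RI {self.ri} outside [0, 100]")


@dataclass
class RIContext:
    """Per-label maximum positive raw SVM score on a reference (training) set."""

    max_raw: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {l: v for l, v in self.max_raw.items() if v <= 0}
        if bad:
            raise ValueError(f"max_raw must be > 0, got {bad}")


def build_ri_context(
    classifiers: list[TrainedClassifier],
    training_vectors: dict[str, FeatureVector],
    annotations: AnnotationDB,
) -> RIContext:
    """Scan each classifier's training positives for its maximum raw score.

    Labels whose positives never score above zero get no entry (their RI
    falls back to 0 at prediction time).
    """
    max_raw: dict[str, float] = {}
    for clf in classifiers:
        label = clf.positive_label
        pos_fvs = [
            fv
            for pid, fv in training_vectors.items()
            if label in annotations.labels.get(pid, frozenset())
        ]
        if not pos_fvs:
            continue
        top = float(max(clf.decision_values_many(pos_fvs)))
        if top > 0:
            max_raw[label] = top
    return RIContext(max_raw)


def ri_svm(raw: float, context: RIContext, label: str) -> int:
    """Rescaled SVM reliability: round(raw*100/max_raw), clamped to [0, 100].

    Non-positive raw scores map to 0. Rounding is to the nearest integer,
    half away from zero.
    """
    if label not in context.max_raw:
        raise KeyError(f"no max_raw recorded for label {label!r}")
    if raw <= 0:
        return 0
    return min(100, int(math.floor(raw * 100.0 / context.max_raw[label] + 0.5)))


def predict(
    query: Profile,
    hits: list[HomologyHit],
    battery: list[TrainedClassifier],
    db: AnnotationDB,
    ri_context: RIContext,
    evalue_threshold: float = EVALUE_SUBNUCLEAR,
    exclude_self: bool = True,
    fv: FeatureVector | None = None,
) -> Prediction:
    """Run the either/or protocol for one query profile."""
    hb = infer(query.id, hits, db, evalue_threshold, exclude_self)
    if hb is not None:
        return Prediction(query.id, hb.labels, ri_hb(hb.pide), "HB")
    if fv is None:
        fv = feature_map(query, battery[0].config.kernel_params)
    scores = decision_values(battery, fv)
    labels = predict_labels(scores)
    if not labels:
        return Prediction(query.id, frozenset(), 0, "NONE", scores=scores)
    top_label = max(labels, key=lambda l: (scores[l], l))
    try:
        ri = ri_svm(scores[top_label], ri_context, top_label)
    except KeyError:
        ri = 0
    return Prediction(query.id, labels, ri, "ML", scores=scores)


def predict_batch(
    queries: list[Profile],
    hits: list[HomologyHit],
    battery: list[TrainedClassifier],
    db: AnnotationDB,
    ri_context: RIContext,
    evalue_threshold: float = EVALUE_SUBNUCLEAR,
    exclude_self: bool = True,
) -> list[Prediction]:
    hits_by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        hits_by_query.setdefault(h.query, []).append(h)
    return [
        predict(
            q,
            hits_by_query.get(q.id, []),
            battery,
            db,
            ri_context,
            evalue_threshold,
            exclude_self,
        )
        for q in queries
    ]
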