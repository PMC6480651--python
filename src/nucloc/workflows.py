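"""End-to-end training / cross-validation workflows tying the pieces together.

These functions implement the stratified five-fold protocol: train the SVM
battery on four folds, predict the held-out fold (optionally routing
through homology transfer first, with donor annotations restricted to the
training folds), and pool the held-out predictions into one confusion
matrix and Q(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ConfusionMatrix, build_confusion, q_n, stratified_kfold
from .homology_inference import (
    EVALUE_SUBNUCLEAR,
    EVALUE_TRAVELER,
    infer,
    infer_traveler,
    ri_hb,
)
from .io_formats import AnnotationDB, HomologyHit, Profile
from .predictor import Prediction, build_ri_context, ri_svm
from .profile_kernel import FeatureVector, feature_map
from .svm_battery import (
    SVMConfig,
    batch_decision_values,
    predict_labels,
    train_battery,
    train_traveler,
)
from .vocabulary import TRAVELER_LABEL

__all__ = ["CVResult", "rarest_label", "cross_validate_battery", "cross_validate_traveler"]


@dataclass
class CVResult:
    """Pooled held-out predictions of a k-fold run."""

    q: float  # overall accuracy Q(n), percent
    predictions: list[Prediction]
    confusion: ConfusionMatrix | None = None


def rarest_label(annotations: AnnotationDB, pid: str) -> str:
    """Stratification key: the protein's globally rarest observed label."""
    counts: dict[str, int] = {}
    for ls in annotations.labels.values():
        for l in ls:
            counts[l] = counts.get(l, 0) + 1
    return min(annotations.labels[pid], key=lambda l: (counts[l], l))


def _restricted_db(annotations: AnnotationDB, ids: set[str]) -> AnnotationDB:
    return AnnotationDB(
        labels={p: ls for p, ls in annotations.labels.items() if p in ids},
        traveler={p: t for p, t in annotations.traveler.items() if p in ids},
    )


def cross_validate_battery(
    profiles: list[Profile],
    annotations: AnnotationDB,
    config: SVMConfig,
    k: int = 5,
    seed: int = 0,
    hits: list[HomologyHit] | None = None,
    evalue_threshold: float = EVALUE_SUBNUCLEAR,
    attribution: str = "top-score",
) -> CVResult:
    """Stratified k-fold cross-validation of the 13-class task.

    With ``hits`` supplied the full either/or protocol runs (homology
    donors limited to the training folds); otherwise predictions are pure
    SVM. Returns pooled Q(n), per-protein predictions and the confusion
    matrix.
    """
    by_id = {p.id: p for p in profiles}
    vectors: dict[str, FeatureVector] = {
        p.id: feature_map(p, config.kernel_params) for p in profiles
    }
    ids = [p.id for p in profiles]
    strat = [rarest_label(annotations, pid) for pid in ids]
    folds = stratified_kfold(ids, strat, k=k, seed=seed)
    hits_by_query: dict[str, list[HomologyHit]] = {}
    for h in hits or []:
        hits_by_query.setdefault(h.query, []).append(h)
    predictions: list[Prediction] = []
    for fold in folds:
        test_ids = set(fold)
        train_ids = [pid for pid in ids if pid not in test_ids]
        train_profiles = [by_id[pid] for pid in train_ids]
        train_vectors = [vectors[pid] for pid in train_ids]
        battery = train_battery(
            train_profiles, annotations, config, vectors=train_vectors
        )
        context = build_ri_context(
            battery, {pid: vectors[pid] for pid in train_ids}, annotations
        )
        train_db = _restricted_db(annotations, set(train_ids))
        test_order = sorted(test_ids)
        score_matrix = batch_decision_values(battery, [vectors[pid] for pid in test_order])
        for i, pid in enumerate(test_order):
            hb = infer(
                pid, hits_by_query.get(pid, []), train_db, evalue_threshold
            )
            if hb is not None:
                predictions.append(Prediction(pid, hb.labels, ri_hb(hb.pide), "HB"))
                continue
            scores = {label: float(s[i]) for label, s in score_matrix.items()}
            labels = predict_labels(scores)
            if not labels:
                predictions.append(Prediction(pid, frozenset(), 0, "NONE", scores=scores))
                continue
            top = max(labels, key=lambda l: (scores[l], l))
            try:
                ri = ri_svm(scores[top], context, top)
            except KeyError:
                ri = 0
            predictions.append(Prediction(pid, labels, ri, "ML", scores=scores))
    confusion = build_confusion(annotations, predictions, attribution)
    return CVResult(q=q_n(confusion), predictions=predictions, confusion=confusion)


def cross_validate_traveler(
    profiles: list[Profile],
    annotations: AnnotationDB,
    config: SVMConfig | None = None,
    k: int = 5,
    seed: int = 0,
    hits: list[HomologyHit] | None = None,
    evalue_threshold: float = EVALUE_TRAVELER,
) -> CVResult:
    """Stratified k-fold cross-validation of the traveler task (Q2)."""
    if config is None:
        config = SVMConfig(class_weighting="none")
    by_id = {p.id: p for p in profiles}
    vectors = {p.id: feature_map(p, config.kernel_params) for p in profiles}
    ids = [p.id for p in profiles]
    strat = [str(annotations.traveler[pid]) for pid in ids]
    folds = stratified_kfold(ids, strat, k=k, seed=seed)
    hits_by_query: dict[str, list[HomologyHit]] = {}
    for h in hits or []:
        hits_by_query.setdefault(h.query, []).append(h)
    predictions: list[Prediction] = []
    correct = 0
    for fold in folds:
        test_ids = set(fold)
        train_ids = [pid for pid in ids if pid not in test_ids]
        clf = train_traveler(
            [by_id[pid] for pid in train_ids],
            annotations,
            config,
            vectors=[vectors[pid] for pid in train_ids],
        )
        pos_fvs = [vectors[pid] for pid in train_ids if annotations.traveler[pid]]
        top = float(max(clf.decision_values_many(pos_fvs))) if pos_fvs else 0.0
        train_db = _restricted_db(annotations, set(train_ids))
        test_order = sorted(test_ids)
        raws = clf.decision_values_many([vectors[pid] for pid in test_order])
        for i, pid in enumerate(test_order):
            hb = infer_traveler(
                pid, hits_by_query.get(pid, []), train_db, evalue_threshold
            ) if hits_by_query else None
            if hb is not None:
                is_traveler = bool(hb.traveler)
                ri = ri_hb(hb.pide)
                source = "HB"
            else:
                raw = float(raws[i])
                is_traveler = raw > 0
                ri = (
                    ri_svm(abs(raw), _ctx(top), TRAVELER_LABEL)
                    if top > 0
                    else 0
                )
                source = "ML"
            labels = frozenset({TRAVELER_LABEL}) if is_traveler else frozenset({"nuclear-only"})
            predictions.append(Prediction(pid, labels, ri, source))
            if is_traveler == annotations.traveler[pid]:
                correct += 1
    q2 = 100.0 * correct / len(predictions)
    return CVResult(q=q2, predictions=predictions)


def _ctx(top: float):
    from .predictor import RIContext

    return RIContext({TRAVELER_LABEL: top})
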