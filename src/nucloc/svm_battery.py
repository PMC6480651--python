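"""One-vs-rest profile-kernel SVMs: 13 compartment classifiers plus a traveler classifier.

Each compartment classifier separates the proteins annotated with one
sub-nuclear label from proteins carrying any of the other twelve; a protein
with several labels is a positive example for each of them. The traveler
classifier separates proteins seen only in the nucleus from those also seen
elsewhere. Training runs on a precomputed (normalized) profile-kernel Gram
matrix; the soft-margin dual problem is solved by scikit-learn's SVC.

Class imbalance is handled by weights inversely proportional to class
frequencies (``class_weighting="inverse-frequency"``); the traveler task is
close to balanced and uses no weights by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .io_formats import AnnotationDB, Profile
from .profile_kernel import (
    FeatureVector,
    KernelParams,
    cross_kernel_matrix,
    feature_map,
    kernel_matrix,
)
from .vocabulary import COMPARTMENTS, TRAVELER_LABEL

__all__ = [
    "SVMConfig",
    "TrainedClassifier",
    "class_weights",
    "train_battery",
    "train_traveler",
    "decision_values",
    "predict_labels",
    "save_battery",
    "load_battery",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SVMConfig:
    """Soft-margin penalty C, stopping tolerance, kernel parameters, weighting."""

    C: float = 10.0
    tol: float = 1e-3
    kernel_params: KernelParams = field(default_factory=KernelParams)
    class_weighting: str = "inverse-frequency"  # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.class_weighting not in ("inverse-frequency", "none"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")


@dataclass
class TrainedClassifier:
    """A binary SVM stored as its support expansion.

    The decision value for a query feature vector x is
    ``sum_i alpha_i * K(sv_i, x) + bias`` over the stored support vectors,
    so the classifier is reproducible from its fields alone.
    """

    positive_label: str
    support_ids: list[str]
    support_vectors: list[FeatureVector]
    dual_coefficients: np.ndarray
    bias: float
    config: SVMConfig
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def _support(self):
        """Cached sparse support matrix and per-vector norms."""
        if "X" not in self._cache:
            from .profile_kernel import feature_matrix

            X = feature_matrix(self.support_vectors)
            self._cache["X"] = X
            self._cache["norms"] = np.sqrt(
                np.array([fv.self_kernel() for fv in self.support_vectors])
            )
        return self._cache["X"], self._cache["norms"]

    def decision_values_many(
        self, fvs: list[FeatureVector], query_matrix=None, query_norms=None
    ) -> np.ndarray:
        """Decision values for many queries; pass a prebuilt query matrix to
        share its construction across the classifiers of a battery."""
        from .profile_kernel import feature_matrix

        Xs, snorm = self._support()
        if query_matrix is None:
            query_matrix = feature_matrix(fvs)
            query_norms = np.sqrt(np.array([fv.self_kernel() for fv in fvs]))
        K = np.asarray((Xs @ query_matrix.T).todense(), dtype=float)
        if self.config.kernel_params.normalize:
            denom = np.outer(snorm, query_norms)
            with np.errstate(divide="ignore", invalid="ignore"):
                K = np.where(denom > 0, K / denom, 0.0)
        return self.dual_coefficients @ K + self.bias

    def decision_value(self, fv: FeatureVector) -> float:
        return float(self.decision_values_many([fv])[0])


def class_weights(n_positive: int, n_negative: int, scheme: str) -> tuple[float, float]:
    """(positive, negative) sample weights.

    Inverse-frequency weighting gives each class weight ``n_total / (2 * n_class)``,
    so a 10-vs-90 split yields a 9:1 positive:negative weight ratio.
    """
    if scheme == "none":
        return 1.0, 1.0
    n = n_positive + n_negative
    return n / (2.0 * n_positive), n / (2.0 * n_negative)


def _fit_one(
    label: str,
    y: np.ndarray,
    gram: np.ndarray,
    ids: list[str],
    vectors: list[FeatureVector],
    config: SVMConfig,
) -> TrainedClassifier | None:
    n_pos = int(y.sum())
    if n_pos == 0:
        warnings.warn(f"class {label!r} has no positive examples; classifier skipped")
        return None
    if n_pos == len(y):
        raise ValueError(f"class {label!r} has no negative examples (degenerate)")
    if n_pos < 2:
        warnings.warn(f"class {label!r} has fewer than 2 positive examples")
    w_pos, w_neg = class_weights(n_pos, len(y) - n_pos, config.class_weighting)
    clf = SVC(
        C=config.C,
        tol=config.tol,
        kernel="precomputed",
        class_weight={1: w_pos, 0: w_neg},
        random_state=config.seed,
    )
    clf.fit(gram, y)
    support = clf.support_
    return TrainedClassifier(
        positive_label=label,
        support_ids=[ids[i] for i in support],
        support_vectors=[vectors[i] for i in support],
        dual_coefficients=np.asarray(clf.dual_coef_[0], dtype=float),
        bias=float(clf.intercept_[0]),
        config=config,
    )


def train_battery(
    profiles: list[Profile],
    annotations: AnnotationDB,
    config: SVMConfig,
    labels: tuple[str, ...] = COMPARTMENTS,
    vectors: list[FeatureVector] | None = None,
) -> list[TrainedClassifier]:
    """Train one-vs-rest classifiers, one per compartment label.

    Multi-label proteins are positives for each of their labels. A label
    with zero positives is skipped with a warning (its decision value is
    treated as -inf downstream).
    """
    missing = [p.id for p in profiles if p.id not in annotations.labels]
    if missing:
        raise ValueError(f"profiles without annotation: {missing[:5]}")
    if vectors is None:
        vectors = [feature_map(p, config.kernel_params) for p in profiles]
    gram = kernel_matrix(profiles, config.kernel_params, vectors=vectors)
    ids = [p.id for p in profiles]
    battery = []
    for label in labels:
        y = np.array([int(label in annotations.labels[pid]) for pid in ids])
        clf = _fit_one(label, y, gram, ids, vectors, config)
        if clf is not None:
            battery.append(clf)
    return battery


def train_traveler(
    profiles: list[Profile],
    annotations: AnnotationDB,
    config: SVMConfig | None = None,
    vectors: list[FeatureVector] | None = None,
) -> TrainedClassifier:
    """Train the nucleus-only vs traveler classifier (unweighted by default)."""
    if config is None:
        config = SVMConfig(class_weighting="none")
    missing = [p.id for p in profiles if p.id not in annotations.traveler]
    if missing:
        raise ValueError(f"profiles without traveler flag: {missing[:5]}")
    if vectors is None:
        vectors = [feature_map(p, config.kernel_params) for p in profiles]
    gram = kernel_matrix(profiles, config.kernel_params, vectors=vectors)
    ids = [p.id for p in profiles]
    y = np.array([int(annotations.traveler[pid]) for pid in ids])
    clf = _fit_one(TRAVELER_LABEL, y, gram, ids, vectors, config)
    if clf is None:
        raise ValueError("traveler task has no positive examples (degenerate)")
    return clf


def decision_values(
    classifiers: list[TrainedClassifier],
    profile: Profile | FeatureVector,
) -> dict[str, float]:
    """Raw decision value per classifier for one query profile."""
    if isinstance(profile, Profile):
        fv = feature_map(profile, classifiers[0].config.kernel_params)
    else:
        fv = profile
    return {label: s[0] for label, s in batch_decision_values(classifiers, [fv]).items()}


def batch_decision_values(
    classifiers: list[TrainedClassifier], fvs: list[FeatureVector]
) -> dict[str, np.ndarray]:
    """Decision values for many queries, building the query matrix once."""
    from .profile_kernel import feature_matrix

    Xq = feature_matrix(fvs)
    qnorm = np.sqrt(np.array([fv.self_kernel() for fv in fvs]))
    return {
        clf.positive_label: clf.decision_values_many(fvs, Xq, qnorm)
        for clf in classifiers
    }


def predict_labels(scores: dict[str, float]) -> frozenset[str]:
    """All labels with a positive decision value; empty set means "None"."""
    return frozenset(label for label, s in scores.items() if s > 0)


# ---------------------------------------------------------------------------
# Serialization (versioned JSON archive with exact round-trip)
# ---------------------------------------------------------------------------

def _clf_to_dict(clf: TrainedClassifier) -> dict:
    return {
        "positive_label": clf.positive_label,
        "support_ids": clf.support_ids,
        "support_vectors": [
            {str(m): c for m, c in fv.counts.items()} for fv in clf.support_vectors
        ],
        "dual_coefficients": [float(x).hex() for x in clf.dual_coefficients],
        "bias": float(clf.bias).hex(),
        "config": {
            "C": clf.config.C,
            "tol": clf.config.tol,
            "class_weighting": clf.config.class_weighting,
            "seed": clf.config.seed,
            "k": clf.config.kernel_params.k,
            "sigma": clf.config.kernel_params.sigma,
            "normalize": clf.config.kernel_params.normalize,
        },
    }


def _clf_from_dict(d: dict) -> TrainedClassifier:
    cfg = d["config"]
    config = SVMConfig(
        C=cfg["C"],
        tol=cfg["tol"],
        kernel_params=KernelParams(cfg["k"], cfg["sigma"], cfg["normalize"]),
        class_weighting=cfg["class_weighting"],
        seed=cfg["seed"],
    )
    k = config.kernel_params.k
    return TrainedClassifier(
        positive_label=d["positive_label"],
        support_ids=list(d["support_ids"]),
        support_vectors=[
            FeatureVector({int(m): int(c) for m, c in sv.items()}, k)
            for sv in d["support_vectors"]
        ],
        dual_coefficients=np.array([float.fromhex(x) for x in d["dual_coefficients"]]),
        bias=float.fromhex(d["bias"]),
        config=config,
    )


def save_battery(classifiers: list[TrainedClassifier], path) -> None:
    """Write classifiers to a versioned JSON archive (floats stored as hex)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "classifiers": [_clf_to_dict(c) for c in classifiers],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_battery(path) -> list[TrainedClassifier]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {payload.get('format_version')}")
    return [_clf_from_dict(d) for d in payload["classifiers"]]
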