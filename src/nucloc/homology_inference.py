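"""Homology-based annotation transfer.

A query inherits the complete label set of its best annotated alignment
hit: among hits passing the E-value threshold (1e-20 for the 13-compartment
task, 1e-5 for the traveler task) whose subject is annotated, the hit with
the highest percent pairwise sequence identity (PIDE) donates its labels.
Self-hits are excluded during performance estimation. The reliability index
of a transfer is a truncated linear function of PIDE.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AnnotationDB, HomologyHit

__all__ = [
    "HBResult",
    "EVALUE_SUBNUCLEAR",
    "EVALUE_TRAVELER",
    "infer",
    "infer_traveler",
    "ri_hb",
]

#: Default E-value threshold for transferring sub-nuclear compartment labels.
EVALUE_SUBNUCLEAR = 1e-20
#: Default E-value threshold for transferring the traveler flag.
EVALUE_TRAVELER = 1e-5


@dataclass(frozen=True)
class HBResult:
    """Labels transferred from the chosen donor hit."""

    labels: frozenset[str]
    pide: float
    subject: str
    traveler: bool | None = None


def _best_hit(
    query: str,
    hits: list[HomologyHit],
    annotated: set[str],
    evalue_threshold: float,
    exclude_self: bool,
) -> HomologyHit | None:
    if evalue_threshold <= 0:
        raise ValueError(f"evalue_threshold must be > 0, got {evalue_threshold}")
    eligible = [
        h
        for h in hits
        if h.query == query
        and h.subject in annotated
        and h.evalue <= evalue_threshold
        and not (exclude_self and h.subject == query)
    ]
    if not eligible:
        return None
    # highest PIDE; ties -> smaller E-value, then lexicographic subject id
    return min(eligible, key=lambda h: (-h.pide, h.evalue, h.subject))


def infer(
    query: str,
    hits: list[HomologyHit],
    db: AnnotationDB,
    evalue_threshold: float = EVALUE_SUBNUCLEAR,
    exclude_self: bool = True,
) -> HBResult | None:
    """Transfer the compartment label set of the highest-PIDE eligible hit.

    Returns ``None`` when no hit passes the filters; the result is invariant
    to the order of the hit list.
    """
    best = _best_hit(query, hits, set(db.labels), evalue_threshold, exclude_self)
    if best is None:
        return None
    return HBResult(frozenset(db.labels[best.subject]), best.pide, best.subject)


def infer_traveler(
    query: str,
    hits: list[HomologyHit],
    db: AnnotationDB,
    evalue_threshold: float = EVALUE_TRAVELER,
    exclude_self: bool = True,
) -> HBResult | None:
    """Transfer the traveler flag of the highest-PIDE eligible hit."""
    best = _best_hit(query, hits, set(db.traveler), evalue_threshold, exclude_self)
    if best is None:
        return None
    return HBResult(frozenset(), best.pide, best.subject, traveler=db.traveler[best.subject])


def ri_hb(pide: float) -> int:
    """Reliability index of a homology transfer: int(10*(PIDE-20)/8), clamped to [0, 100].

    PIDE 20 maps to 0 and PIDE 100 to 100; accepted hits below 20% identity
    clamp to 0 rather than going negative.
    """
    if not 0.0 <= pide <= 100.0:
        raise ValueError(f"pide {pide} outside [0, 100]")
    return max(0, min(100, int(10.0 * (pide - 20.0) / 8.0)))
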