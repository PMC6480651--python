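"""Readers and writers for every external format the toolkit touches.

Formats
-------
- FASTA (via Biopython) for protein sequences.
- PSI-BLAST ASCII PSSM: one row per position with a position index, the
  query residue, 20 integer log-odds columns and 20 percentage columns.
  The reader converts either block into a non-negative per-position
  "conservation cost" matrix (see :func:`read_pssm`).
- BLAST tabular (outfmt-6-like) alignment hits.
- Plain TSV tables for annotations, traveler flags, PPI edges, GO terms,
  predictions, and a native multi-profile cost table.

All TSV formats are tab-delimited UTF-8; lines starting with ``#`` are
comments. Errors carry the offending line number or record id.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .vocabulary import AA_INDEX, AMINO_ACIDS, canonical_compartment

__all__ = [
    "ProteinRecord",
    "Profile",
    "AnnotationDB",
    "HomologyHit",
    "Edge",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_pssm",
    "write_pssm",
    "read_blast_tab",
    "write_blast_tab",
    "read_annotations",
    "write_annotations",
    "read_edges",
    "write_edges",
    "filter_edges",
    "read_go",
    "write_go",
    "read_profiles_tsv",
    "write_profiles_tsv",
    "read_predictions",
    "write_predictions",
]

#: Uniform cost assigned to the unknown residue X: -log(1/20).
X_COST = math.log(20.0)

#: Default pseudo-frequency floor for the -log transform of PSSM percentages.
DEFAULT_PSEUDO_FREQ = 1e-3


class FormatError(ValueError):
    """A malformed input file; the message names the record or line."""


@dataclass
class ProteinRecord:
    """A protein sequence over the 20-letter alphabet (X tolerated)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r} has an empty sequence")


@dataclass
class Profile:
    """Per-protein position x amino-acid conservation-cost matrix.

    ``scores[p, a]`` is a non-negative cost of observing amino acid
    ``AMINO_ACIDS[a]`` at position ``p``; low cost = conserved. The profile
    kernel counts k-mers whose summed cost falls below a threshold, so
    non-negativity is what makes its pruned enumeration exact.
    """

    id: str
    scores: np.ndarray
    source: str = "synthetic"  # {"pssm-derived", "synthetic"}
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(AMINO_ACIDS):
            raise ValueError(
                f"profile {self.id!r}: scores must be L x {len(AMINO_ACIDS)}"
            )
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValueError(f"profile {self.id!r}: scores must be finite and >= 0")
        if self.sequence is not None and len(self.sequence) != self.scores.shape[0]:
            raise ValueError(
                f"profile {self.id!r}: sequence length {len(self.sequence)} "
                f"!= profile length {self.scores.shape[0]}"
            )

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])


@dataclass
class AnnotationDB:
    """Protein -> compartment-label set, plus the traveler flag."""

    labels: dict[str, frozenset[str]] = field(default_factory=dict)
    traveler: dict[str, bool] = field(default_factory=dict)

    def add_label(self, protein: str, label: str) -> None:
        if not protein:
            raise FormatError("annotation with empty protein id")
        label = canonical_compartment(label)
        current = self.labels.get(protein, frozenset())
        self.labels[protein] = current | {label}

    def ids(self) -> list[str]:
        return sorted(set(self.labels) | set(self.traveler))


@dataclass(frozen=True)
class HomologyHit:
    """One tabular alignment hit: query, subject, %identity, E-value."""

    query: str
    subject: str
    pide: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pide <= 100.0:
            raise ValueError(f"hit {self.query}->{self.subject}: pide {self.pide} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"hit {self.query}->{self.subject}: negative E-value {self.evalue}")


@dataclass(frozen=True)
class Edge:
    """One PPI edge with the evidence fields used by the interaction filter."""

    u: str
    v: str
    interaction_type: str = "direct"  # "direct" (binary) vs "association"
    y2h: bool = False
    pubmed_ids: tuple[str, ...] = ()

    @property
    def is_self_loop(self) -> bool:
        return self.u == self.v


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file; sequences are uppercased, gaps/whitespace stripped."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        seq = "".join(seq.split())
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def _is_pssm_row(fields: list[str]) -> bool:
    return (
        len(fields) >= 42
        and fields[0].isdigit()
        and len(fields[1]) == 1
        and fields[1].isalpha()
    )


def read_pssm(
    path: str | Path,
    profile_id: str | None = None,
    columns: str = "frequency",
    pseudo_freq: float = DEFAULT_PSEUDO_FREQ,
) -> Profile:
    """Parse a PSI-BLAST ASCII PSSM into a conservation-cost :class:`Profile`.

    Parameters
    ----------
    columns:
        ``"frequency"`` (default) derives costs from the percentage block:
        ``cost = -log(max(pct/100, pseudo_freq))``, clipped at 0, so a fully
        conserved residue costs 0 and an unobserved one costs
        ``-log(pseudo_freq)``. ``"logodds"`` uses the integer log-odds block:
        ``cost = max(0, -logodds)``, i.e. favoured residues are free and
        disfavoured ones cost their negated score.
    """
    if columns not in ("frequency", "logodds"):
        raise ValueError(f"columns must be 'frequency' or 'logodds', got {columns!r}")
    path = Path(path)
    rows: list[np.ndarray] = []
    sequence: list[str] = []
    expected_index = 1
    last_line = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not _is_pssm_row(fields):
                continue
            last_line = lineno
            idx = int(fields[0])
            if idx != expected_index:
                raise FormatError(
                    f"{path}:{lineno}: position index {idx}, expected {expected_index}"
                )
            expected_index += 1
            sequence.append(fields[1].upper())
            block = fields[2:22] if columns == "logodds" else fields[22:42]
            try:
                values = np.array([float(x) for x in block], dtype=float)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if columns == "frequency":
                freq = np.maximum(values / 100.0, pseudo_freq)
                cost = np.clip(-np.log(freq), 0.0, None)
            else:
                cost = np.clip(-values, 0.0, None)
            rows.append(cost)
    if not rows:
        raise FormatError(
            f"{path}: no PSSM rows parsed (last line examined: {last_line})"
        )
    return Profile(
        id=profile_id or path.stem,
        scores=np.vstack(rows),
        source="pssm-derived",
        sequence="".join(sequence),
    )


def write_pssm(profile: Profile, path: str | Path, pseudo_freq: float = DEFAULT_PSEUDO_FREQ) -> None:
    """Write a profile back to the PSI-BLAST ASCII layout.

    The percentage block is emitted with full precision (``%.12g``), so
    ``read_pssm(write_pssm(p))`` reproduces the cost matrix to <= 1e-9 for
    costs below the ``-log(pseudo_freq)`` cap.
    """
    seq = profile.sequence or "X" * profile.length
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write(" " * 11 + "  ".join(AMINO_ACIDS) + "   " + "  ".join(AMINO_ACIDS) + "\n")
        for i in range(profile.length):
            freq = np.exp(-profile.scores[i])
            freq = np.maximum(freq, pseudo_freq)
            logodds = np.round(-profile.scores[i]).astype(int)
            cells = " ".join(str(v) for v in logodds)
            pcts = " ".join(f"{100.0 * f:.12g}" for f in freq)
            fh.write(f"{i + 1:5d} {seq[i]} {cells} {pcts} 0.00 0.00\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tab(
    path: str | Path,
    query_col: int = 0,
    subject_col: int = 1,
    pident_col: int = 2,
    evalue_col: int = 10,
) -> list[HomologyHit]:
    """Read tabular alignment hits (standard 12-column outfmt-6 by default)."""
    hits: list[HomologyHit] = []
    max_col = max(query_col, subject_col, pident_col, evalue_col)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= max_col:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {max_col + 1} columns, got {len(fields)}"
                )
            try:
                pide = float(fields[pident_col])
                evalue = float(fields[evalue_col])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric pident/evalue") from None
            try:
                hits.append(HomologyHit(fields[query_col], fields[subject_col], pide, evalue))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_blast_tab(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in a 12-column layout (unused columns zero-filled)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            cols = [h.query, h.subject, f"{h.pide:g}", "0", "0", "0", "0", "0", "0", "0",
                    f"{h.evalue:g}", "0"]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Annotation / edge / GO TSVs
# ---------------------------------------------------------------------------

def _tsv_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_annotations(
    labels_path: str | Path | None = None,
    traveler_path: str | Path | None = None,
) -> AnnotationDB:
    """Read compartment labels ("id<TAB>label" lines) and/or traveler flags.

    Duplicate lines merge; labels are matched to the 13-compartment
    vocabulary case-insensitively.
    """
    db = AnnotationDB()
    if labels_path is not None:
        for lineno, fields in _tsv_lines(labels_path):
            if len(fields) < 2:
                raise FormatError(f"{labels_path}:{lineno}: expected 'id<TAB>label'")
            try:
                db.add_label(fields[0], fields[1])
            except ValueError as exc:
                raise FormatError(f"{labels_path}:{lineno}: {exc}") from None
    if traveler_path is not None:
        truthy = {"1", "true", "yes"}
        falsy = {"0", "false", "no"}
        for lineno, fields in _tsv_lines(traveler_path):
            if len(fields) < 2:
                raise FormatError(f"{traveler_path}:{lineno}: expected 'id<TAB>flag'")
            flag = fields[1].strip().lower()
            if flag not in truthy | falsy:
                raise FormatError(f"{traveler_path}:{lineno}: flag must be 0/1/true/false")
            db.traveler[fields[0]] = flag in truthy
    return db


def write_annotations(db: AnnotationDB, labels_path: str | Path, traveler_path: str | Path | None = None) -> None:
    with open(labels_path, "w", encoding="utf-8") as fh:
        for pid in sorted(db.labels):
            for label in sorted(db.labels[pid]):
                fh.write(f"{pid}\t{label}\n")
    if traveler_path is not None:
        with open(traveler_path, "w", encoding="utf-8") as fh:
            for pid in sorted(db.traveler):
                fh.write(f"{pid}\t{int(db.traveler[pid])}\n")


def read_edges(path: str | Path) -> list[Edge]:
    """Read a PPI edge TSV: u, v [, interaction_type, y2h, pubmed_ids].

    Self-loops are accepted but flagged with a warning; downstream network
    statistics exclude them.
    """
    edges: list[Edge] = []
    for lineno, fields in _tsv_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected at least 'u<TAB>v'")
        itype = fields[2].strip().lower() if len(fields) > 2 and fields[2] else "direct"
        y2h = fields[3].strip().lower() in {"1", "true", "yes"} if len(fields) > 3 else False
        pubmeds: tuple[str, ...] = ()
        if len(fields) > 4 and fields[4]:
            pubmeds = tuple(p for p in fields[4].split(",") if p)
        edge = Edge(fields[0], fields[1], itype, y2h, pubmeds)
        if edge.is_self_loop:
            warnings.warn(f"{path}:{lineno}: self-loop edge {edge.u!r} (excluded from PPI statistics)")
        edges.append(edge)
    return edges


def write_edges(edges: Iterable[Edge], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in edges:
            fh.write(
                f"{e.u}\t{e.v}\t{e.interaction_type}\t{int(e.y2h)}\t{','.join(e.pubmed_ids)}\n"
            )


def filter_edges(edges: Iterable[Edge]) -> list[Edge]:
    """Keep binary/direct interactions validated by Y2H or >= 2 PubMed ids."""
    return [
        e
        for e in edges
        if e.interaction_type == "direct" and (e.y2h or len(e.pubmed_ids) >= 2)
    ]


def read_go(path: str | Path) -> dict[str, set[str]]:
    """Read a flat GO annotation TSV ("id<TAB>GO:NNNNNNN")."""
    go: dict[str, set[str]] = {}
    for lineno, fields in _tsv_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'id<TAB>term'")
        go.setdefault(fields[0], set()).add(fields[1])
    return go


def write_go(go: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(go):
            for term in sorted(go[pid]):
                fh.write(f"{pid}\t{term}\n")


# ---------------------------------------------------------------------------
# Native multi-profile cost TSV
# ---------------------------------------------------------------------------

def write_profiles_tsv(profiles: Iterable[Profile], path: str | Path) -> None:
    """Write profiles as TSV rows: id, position (1-based), 20 cost columns."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#id\tposition\t" + "\t".join(AMINO_ACIDS) + "\n")
        for p in profiles:
            for i in range(p.length):
                costs = "\t".join(f"{c:.12g}" for c in p.scores[i])
                fh.write(f"{p.id}\t{i + 1}\t{costs}\n")


def read_profiles_tsv(path: str | Path) -> list[Profile]:
    rows: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    n_aa = len(AMINO_ACIDS)
    for lineno, fields in _tsv_lines(path):
        if len(fields) != 2 + n_aa:
            raise FormatError(f"{path}:{lineno}: expected {2 + n_aa} columns")
        pid = fields[0]
        try:
            pos = int(fields[1])
            costs = np.array([float(x) for x in fields[2:]], dtype=float)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric cell") from None
        if pid not in rows:
            rows[pid] = []
            order.append(pid)
        if pos != len(rows[pid]) + 1:
            raise FormatError(f"{path}:{lineno}: position {pos} out of order for {pid!r}")
        rows[pid].append(costs)
    return [Profile(pid, np.vstack(rows[pid]), source="synthetic") for pid in order]


# ---------------------------------------------------------------------------
# Prediction TSV (protein, ;-joined labels, RI, source)
# ---------------------------------------------------------------------------

def write_predictions(predictions, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein\tlabels\tri\tsource\n")
        for p in predictions:
            labels = ";".join(sorted(p.labels))
            fh.write(f"{p.protein}\t{labels}\t{p.ri}\t{p.source}\n")


def read_predictions(path: str | Path):
    from .predictor import Prediction  # local import: avoid a cycle

    out = []
    for lineno, fields in _tsv_lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        labels = frozenset(x for x in fields[1].split(";") if x)
        try:
            ri = int(fields[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer RI") from None
        out.append(Prediction(fields[0], labels, ri, fields[3]))
    return out
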