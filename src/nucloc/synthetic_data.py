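"""Generators for synthetic inputs with the statistical structure the method assumes.

Profiles get class-specific conserved k-mers ("motifs") planted at random
positions: at a motif column the motif residue costs ``motif_strength``
(default 0, i.e. perfectly conserved) and every other residue costs
``off_motif_cost``; background columns draw i.i.d. costs from a uniform
distribution. With the default kernel threshold, exact motif windows are
conserved while all-background windows are not, so the profile kernel sees
class-separating counts whose ground truth the generator records.

Homology tables give a configurable fraction of queries an annotated
same-class donor below the E-value threshold; PPI networks draw
within/between-compartment edges at two rates; GO tables enrich one
designated term per compartment at a configurable odds ratio.

All generators are pure functions of their config (the seed lives in the
config; each generator uses an independent stream derived from it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    AnnotationDB,
    Edge,
    HomologyHit,
    Profile,
    write_annotations,
    write_blast_tab,
    write_edges,
    write_go,
    write_profiles_tsv,
)
from .vocabulary import AMINO_ACIDS, COMPARTMENTS

__all__ = ["GeneratorConfig", "gen_profiles", "gen_homology", "gen_ppi", "gen_go", "simulate_all"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    Defaults emulate the regime the method targets: 13 compartment classes
    of 20 proteins each, profiles of 60 positions carrying 3 strongly
    conserved class motifs of length 4, 15% multi-label proteins, a roughly
    balanced traveler split, homologs with known annotation for half the
    queries at 40-95% identity, and a PPI network whose within-compartment
    edge rate is four times the between rate.
    """

    n_classes: int = 13
    n_per_class: int | Sequence[int] = 20
    profile_length: int = 60
    motif_k: int = 4
    n_motif_sites: int = 3
    motif_strength: float = 0.0
    background_cost: tuple[float, float] = (2.0, 4.0)
    off_motif_cost: float = 4.0
    multilabel_fraction: float = 0.15
    traveler_fraction: float = 0.5
    class_decay: float = 1.0  # < 1 gives geometrically shrinking class sizes
    homolog_coverage: float = 0.5
    pide_range: tuple[float, float] = (40.0, 95.0)
    hit_evalue: float = 1e-30
    decoy_evalue: float = 1e-3
    within_ppi_rate: float = 0.2
    between_ppi_rate: float = 0.05
    enriched_term_odds: float = 8.0
    go_base_prob: float = 0.15
    n_filler_terms: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("multilabel_fraction", "traveler_fraction", "homolog_coverage",
                     "within_ppi_rate", "between_ppi_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 1 <= self.n_classes <= len(COMPARTMENTS):
            raise ValueError(f"n_classes must be in [1, {len(COMPARTMENTS)}]")
        if self.motif_k > self.profile_length:
            raise ValueError("motif_k exceeds profile_length")

    @property
    def class_labels(self) -> tuple[str, ...]:
        return COMPARTMENTS[: self.n_classes]

    def class_sizes(self) -> list[int]:
        if isinstance(self.n_per_class, int):
            return [
                max(0, round(self.n_per_class * self.class_decay**c))
                for c in range(self.n_classes)
            ]
        sizes = list(self.n_per_class)
        if len(sizes) != self.n_classes:
            raise ValueError("n_per_class sequence must have n_classes entries")
        return sizes


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _draw_motifs(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, str]:
    """Distinct k-mer per class plus one for the traveler signature."""
    motifs: dict[str, str] = {}
    used: set[str] = set()
    for label in list(config.class_labels) + ["traveler"]:
        while True:
            kmer = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, config.motif_k))
            if kmer not in used:
                used.add(kmer)
                motifs[label] = kmer
                break
    return motifs


def _place_sites(
    rng: np.random.Generator, length: int, k: int, n_sites: int, taken: list[int]
) -> list[int]:
    """Pick window starts separated by >= 2k-1 from every other site.

    The separation guarantees no length-k window spans two planted sites,
    so conserved-k-mer counts decompose exactly per site.
    """
    candidates = rng.permutation(length - k + 1)
    sites: list[int] = []
    for start in candidates:
        start = int(start)
        if all(abs(start - t) >= 2 * k - 1 for t in taken + sites):
            sites.append(start)
            if len(sites) == n_sites:
                break
    return sites


def gen_profiles(config: GeneratorConfig) -> tuple[list[Profile], AnnotationDB, dict]:
    """Synthesize profiles with planted class motifs.

    Returns (profiles, annotations, truth); ``truth`` records the motif
    strings, per-protein planted sites, and the traveler signature, so
    tests can compare kernel counts against generator bookkeeping.
    """
    rng = _rng(config, 0)
    motifs = _draw_motifs(config, rng)
    labels = config.class_labels
    sizes = config.class_sizes()
    lo, hi = config.background_cost
    profiles: list[Profile] = []
    db = AnnotationDB()
    truth: dict = {"motifs": dict(motifs), "sites": {}, "classes": {}}
    counter = 0
    for c, label in enumerate(labels):
        for _ in range(sizes[c]):
            pid = f"P{counter:04d}"
            counter += 1
            protein_labels = [label]
            if config.n_classes > 1 and rng.random() < config.multilabel_fraction:
                other = int(rng.integers(0, config.n_classes - 1))
                if other >= c:
                    other += 1
                protein_labels.append(labels[other])
            is_traveler = bool(rng.random() < config.traveler_fraction)
            scores = rng.uniform(lo, hi, size=(config.profile_length, 20))
            taken: list[int] = []
            site_map: dict[str, list[int]] = {}
            planted = protein_labels + (["traveler"] if is_traveler else [])
            for m_label in planted:
                sites = _place_sites(
                    rng, config.profile_length, config.motif_k, config.n_motif_sites, taken
                )
                taken.extend(sites)
                site_map[m_label] = sites
                kmer = motifs[m_label]
                for start in sites:
                    for j, aa in enumerate(kmer):
                        scores[start + j, :] = config.off_motif_cost
                        scores[start + j, AMINO_ACIDS.index(aa)] = config.motif_strength
            profiles.append(Profile(pid, scores, source="synthetic"))
            for l in protein_labels:
                db.add_label(pid, l)
            db.traveler[pid] = is_traveler
            truth["sites"][pid] = site_map
            truth["classes"][pid] = list(protein_labels)
    return profiles, db, truth


def gen_homology(config: GeneratorConfig, db: AnnotationDB) -> list[HomologyHit]:
    """Synthetic alignment hits.

    A ``homolog_coverage`` fraction of queries gets a below-threshold hit to
    a distinct annotated subject with the same label set (falling back to a
    shared first label); the rest get either an above-threshold decoy or
    nothing.
    """
    rng = _rng(config, 1)
    ids = sorted(db.labels)
    by_labelset: dict[frozenset[str], list[str]] = {}
    by_first: dict[str, list[str]] = {}
    for pid in ids:
        by_labelset.setdefault(db.labels[pid], []).append(pid)
        by_first.setdefault(min(db.labels[pid]), []).append(pid)
    hits: list[HomologyHit] = []
    lo, hi = config.pide_range
    for pid in ids:
        if rng.random() < config.homolog_coverage:
            pool = [s for s in by_labelset[db.labels[pid]] if s != pid]
            if not pool:
                pool = [s for s in by_first[min(db.labels[pid])] if s != pid]
            if not pool:
                continue
            subject = pool[int(rng.integers(0, len(pool)))]
            hits.append(HomologyHit(pid, subject, float(rng.uniform(lo, hi)), config.hit_evalue))
        elif rng.random() < 0.5:
            subject = ids[int(rng.integers(0, len(ids)))]
            if subject != pid:
                hits.append(
                    HomologyHit(pid, subject, float(rng.uniform(20.0, 40.0)), config.decoy_evalue)
                )
    return hits


def gen_ppi(config: GeneratorConfig, compartment_map: Mapping[str, frozenset[str]]) -> list[Edge]:
    """Bernoulli edges: within-compartment pairs at ``within_ppi_rate``,
    cross-compartment pairs at ``between_ppi_rate``; evidence columns are
    populated to pass the binary/direct interaction filter."""
    rng = _rng(config, 2)
    ids = sorted(compartment_map)
    edges: list[Edge] = []
    for i, u in enumerate(ids):
        for v in ids[i + 1 :]:
            shared = set(compartment_map[u]) & set(compartment_map[v])
            rate = config.within_ppi_rate if shared else config.between_ppi_rate
            if rng.random() < rate:
                edges.append(Edge(u, v, "direct", True, ()))
    return edges


def gen_go(
    config: GeneratorConfig, compartment_map: Mapping[str, frozenset[str]]
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GO annotations with one designated enriched term per compartment.

    Members of compartment c carry its designated term with odds
    ``enriched_term_odds`` relative to the base probability; filler terms
    are annotated uniformly. Returns (go_map, designated-term-per-label).
    """
    rng = _rng(config, 3)
    ids = sorted(compartment_map)
    p0 = config.go_base_prob
    r = p0 / (1.0 - p0) * config.enriched_term_odds
    p1 = r / (1.0 + r)
    designated = {
        label: f"GO:1{c:06d}" for c, label in enumerate(config.class_labels)
    }
    go: dict[str, set[str]] = {pid: set() for pid in ids}
    for c, label in enumerate(config.class_labels):
        term = designated[label]
        for pid in ids:
            p = p1 if label in compartment_map[pid] else p0
            if rng.random() < p:
                go[pid].add(term)
    for f in range(config.n_filler_terms):
        term = f"GO:2{f:06d}"
        for pid in ids:
            if rng.random() < p0:
                go[pid].add(term)
    return go, designated


def simulate_all(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete fixture directory: profiles, annotations, hits,
    edges, GO terms, and a truth manifest. Returns the path map."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles, db, truth = gen_profiles(config)
    hits = gen_homology(config, db)
    edges = gen_ppi(config, db.labels)
    go, designated = gen_go(config, db.labels)
    paths = {
        "profiles": out / "profiles.tsv",
        "annotations": out / "annotations.tsv",
        "traveler": out / "traveler.tsv",
        "hits": out / "hits.tsv",
        "edges": out / "edges.tsv",
        "go": out / "go.tsv",
        "truth": out / "truth.json",
    }
    write_profiles_tsv(profiles, paths["profiles"])
    write_annotations(db, paths["annotations"], paths["traveler"])
    write_blast_tab(hits, paths["hits"])
    write_edges(edges, paths["edges"])
    write_go(go, paths["go"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump({**truth, "designated_go_terms": designated}, fh, indent=1)
    return paths
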