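"""GO biological-process enrichment and PPI network analytics.

Enrichment of a protein set against a background uses the upper-tail
hypergeometric test per GO term, with Benjamini-Hochberg adjustment across
terms and a significance call at adjusted p < 0.01.

The PPI odds ratio asks whether proteins in compartments i and j interact
more often than expected: odds(i,j) = num_obs(i,j) / num_exp(i,j), where
num_exp distributes the total observed interaction mass proportionally to
the number of *possible* pairs between the compartments. Multi-compartment
proteins contribute to every compartment pair they can realize, with the
same counting rule in the numerator and denominator so that a uniformly
random network has odds 1 everywhere.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import Edge
from .vocabulary import COMPARTMENTS

__all__ = [
    "EnrichmentResult",
    "PPICounts",
    "hypergeometric_pvalue",
    "hypergeom_enrichment",
    "bh_adjust",
    "build_ppi_graph",
    "ppi_pair_counts",
    "ppi_odds",
    "degree_stats",
    "SIGNIFICANCE_ALPHA",
]

#: Adjusted-p threshold for calling a term significantly enriched.
SIGNIFICANCE_ALPHA = 0.01


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap: int
    target_size: int
    background_count: int
    background_size: int
    p_value: float
    q_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= min(self.target_size, self.background_count):
            raise ValueError(f"term {self.term}: impossible overlap {self.overlap}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"term {self.term}: p-value {self.p_value} outside [0, 1]")
        if self.q_value < self.p_value - 1e-12:
            raise ValueError(f"term {self.term}: q < p")


def hypergeometric_pvalue(overlap: int, background_size: int, background_count: int, target_size: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(overlap - 1, background_size, background_count, target_size))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(
    target: Iterable[str],
    background: Iterable[str],
    go_map: Mapping[str, Iterable[str]],
    alpha: float = SIGNIFICANCE_ALPHA,
) -> list[EnrichmentResult]:
    """Per-term enrichment of ``target`` within ``background``, BH-adjusted.

    Terms are collected from the background's annotations; a term annotating
    no background protein is skipped with a warning. Results are sorted by
    ascending p-value (ties by term id).
    """
    target = set(target)
    background = set(background)
    if not target <= background:
        raise ValueError("target must be a subset of background")
    term_members: dict[str, set[str]] = {}
    for pid in background:
        for term in go_map.get(pid, ()):
            term_members.setdefault(term, set()).add(pid)
    terms = sorted(term_members)
    if not terms:
        warnings.warn("no GO terms annotate the background")
        return []
    N, n = len(background), len(target)
    pvals = []
    for term in terms:
        members = term_members[term]
        pvals.append(hypergeometric_pvalue(len(members & target), N, len(members), n))
    qvals = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            term=term,
            overlap=len(term_members[term] & target),
            target_size=n,
            background_count=len(term_members[term]),
            background_size=N,
            p_value=p,
            q_value=q,
            significant=bool(q < alpha),
        )
        for term, p, q in zip(terms, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

@dataclass
class PPICounts:
    """Observed/possible pair counts per compartment pair, plus the total."""

    num_obs: pd.DataFrame
    num_pos: pd.DataFrame
    num_obs_total: float

    def num_exp(self) -> pd.DataFrame:
        total_pos = _upper_sum(self.num_pos)
        if total_pos == 0:
            raise ValueError("no possible compartment pairs")
        return self.num_pos / total_pos * self.num_obs_total


def _upper_sum(df: pd.DataFrame) -> float:
    """Sum over unordered compartment-pair cells (diagonal once)."""
    a = df.to_numpy()
    return float(np.triu(a).sum())


def build_ppi_graph(
    edges: Iterable[Edge | tuple[str, str]],
    compartments: Mapping[str, Iterable[str]] | None = None,
    groups: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Undirected PPI graph; self-loops dropped, duplicate edges merged.

    Node attributes: ``compartments`` (frozenset, possibly empty) and
    ``group`` (e.g. nuclear-only / traveler / non-nuclear).
    """
    g = nx.Graph()
    for e in edges:
        u, v = (e.u, e.v) if isinstance(e, Edge) else e
        if u == v:
            continue
        g.add_edge(u, v)
    for node in g.nodes:
        g.nodes[node]["compartments"] = frozenset(
            (compartments or {}).get(node, frozenset())
        )
        g.nodes[node]["group"] = (groups or {}).get(node)
    return g


def _pair_cells(lu: frozenset[str], lv: frozenset[str]) -> set[tuple[str, str]]:
    """Unordered compartment pairs realizable by a protein pair (each once)."""
    cells = set()
    for i in lu:
        for j in lv:
            cells.add((i, j) if i <= j else (j, i))
    return cells


def ppi_pair_counts(
    graph: nx.Graph,
    labels: Sequence[str] = COMPARTMENTS,
) -> PPICounts:
    """Enumerate possible and observed pairs per compartment pair.

    A protein pair (u, v) counts once toward every unordered compartment
    pair {i, j} with i in u's labels and j in v's labels (or vice versa);
    the identical rule applies to observed edges, and the total observed
    mass is the sum over cells, which keeps expected counts consistent.
    """
    comp = {n: graph.nodes[n]["compartments"] for n in graph.nodes}
    labeled = sorted(n for n, ls in comp.items() if ls)
    idx = list(labels)
    pos = pd.DataFrame(0.0, index=idx, columns=idx)
    obs = pd.DataFrame(0.0, index=idx, columns=idx)

    def add(df: pd.DataFrame, u: str, v: str) -> None:
        for i, j in _pair_cells(comp[u], comp[v]):
            df.at[i, j] += 1.0
            if i != j:
                df.at[j, i] += 1.0

    for u, v in itertools.combinations(labeled, 2):
        add(pos, u, v)
    for u, v in graph.edges:
        if comp.get(u) and comp.get(v):
            add(obs, u, v)
    return PPICounts(obs, pos, _upper_sum(obs))


def ppi_odds(
    graph: nx.Graph,
    labels: Sequence[str] = COMPARTMENTS,
) -> pd.DataFrame:
    """Symmetric 13x13 odds-ratio matrix; NaN where no pair is possible."""
    counts = ppi_pair_counts(graph, labels)
    if counts.num_obs_total == 0:
        raise ValueError("no observed edges among compartment-labeled nodes")
    exp = counts.num_exp()
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = counts.num_obs / exp
    return odds.where(exp > 0)


def degree_stats(graph: nx.Graph) -> dict:
    """Mean degree per node group, component census, largest-component shares."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = dict(graph.degree())
    by_group: dict[str, list[int]] = {}
    for n, d in degrees.items():
        by_group.setdefault(graph.nodes[n].get("group") or "ungrouped", []).append(d)
    components = sorted((len(c) for c in nx.connected_components(graph)), reverse=True)
    largest = max(nx.connected_components(graph), key=len)
    frac_in_largest = {}
    for grp, ds in by_group.items():
        members = [n for n in graph.nodes if (graph.nodes[n].get("group") or "ungrouped") == grp]
        frac_in_largest[grp] = sum(1 for n in members if n in largest) / len(members)
    return {
        "mean_degree": {grp: float(np.mean(ds)) for grp, ds in by_group.items()},
        "n_components": len(components),
        "component_sizes": components,
        "fraction_in_largest_component": frac_in_largest,
    }
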