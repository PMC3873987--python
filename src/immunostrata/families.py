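"""Paralog detection and family partitioning by iterative bridge removal.

Two genes form a paralog edge when they share reciprocal self-proteome blastp
hits that (i) have e-values <= 1e-4, (ii) have at least 30% positives,
(iii) align over at least half of the *longer* protein, and (iv) are each more
significant than their query gene's best non-Hymenopteran hit (vacuously true
for genes with no such hit).  Families are then the connected components of
the paralog graph after repeatedly deleting, from components larger than two,
the bridge with the globally lowest edge bitscore.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io_tables import BlastHit

__all__ = [
    "ParalogEdge",
    "ParalogFamily",
    "ParalogCriteria",
    "paralog_edges",
    "build_families",
    "multi_copy_flags",
]


@dataclass(frozen=True)
class ParalogCriteria:
    max_evalue: float = 1e-4
    min_pct_positives: float = 30.0
    min_coverage_of_longer: float = 0.5


@dataclass(frozen=True)
class ParalogEdge:
    """An undirected paralog edge; gene_a < gene_b lexicographically."""

    gene_a: str
    gene_b: str
    bitscore_ab: float
    bitscore_ba: float

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must be lexicographically smaller than gene_b")

    @property
    def edge_bitscore(self) -> float:
        # an edge stands for two directional hits; the max is used for removal order
        return max(self.bitscore_ab, self.bitscore_ba)


@dataclass(frozen=True)
class ParalogFamily:
    family_id: str
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


def _passes(hit: BlastHit, criteria: ParalogCriteria) -> bool:
    longer = max(hit.query_len, hit.subject_len)
    return (
        hit.evalue <= criteria.max_evalue
        and hit.pct_positives >= criteria.min_pct_positives
        and hit.align_len >= criteria.min_coverage_of_longer * longer
    )


def paralog_edges(
    self_hits: Sequence[BlastHit],
    best_nonhym_evalue: Mapping[str, float],
    criteria: ParalogCriteria | None = None,
) -> list[ParalogEdge]:
    """Build paralog edges from gene-level self-proteome hits.

    ``self_hits`` must be gene-level (query and subject are gene ids) with
    self-matches removed.  ``best_nonhym_evalue`` maps a gene to the e-value of
    its most significant hit to any non-Hymenopteran species; genes absent
    from the map have no such hit and pass condition (iv) vacuously.  Both
    directional hits must pass every condition, each compared against its own
    query gene's non-Hymenopteran best.
    """
    criteria = criteria or ParalogCriteria()
    directed: dict[tuple[str, str], BlastHit] = {}
    for hit in self_hits:
        if hit.query_protein == hit.subject_protein:
            continue  # self-match; never a paralog edge
        key = (hit.query_protein, hit.subject_protein)
        # keep the most significant directional hit per ordered pair
        old = directed.get(key)
        if old is None or (hit.evalue, -hit.bitscore) < (old.evalue, -old.bitscore):
            directed[key] = hit

    def beats_nonhym(hit: BlastHit) -> bool:
        cutoff = best_nonhym_evalue.get(hit.query_protein)
        return cutoff is None or hit.evalue < cutoff

    edges = []
    for (a, b), ab in directed.items():
        if a >= b:
            continue
        ba = directed.get((b, a))
        if ba is None:
            continue
        if not (_passes(ab, criteria) and _passes(ba, criteria)):
            continue
        if not (beats_nonhym(ab) and beats_nonhym(ba)):
            continue
        edges.append(ParalogEdge(a, b, ab.bitscore, ba.bitscore))
    return sorted(edges, key=lambda e: (e.gene_a, e.gene_b))


def build_families(
    edges: Sequence[ParalogEdge],
    genes: Iterable[str],
) -> list[ParalogFamily]:
    """Partition genes into families by iterative lowest-bitscore bridge removal.

    Starting from the connected components of the paralog graph, repeatedly
    find all bridges inside components of size > 2 and delete the one with the
    globally lowest edge bitscore (ties: lexicographically smallest gene
    pair), until no such bridge remains.  Components of size <= 2 are never
    split.  Edge-less genes become singleton families.  Family ids are
    assigned deterministically in lexicographic order of the smallest member.
    """
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for e in edges:
        for g in (e.gene_a, e.gene_b):
            if g not in graph:
                raise KeyError(f"edge references gene {g!r} outside the universe")
        graph.add_edge(e.gene_a, e.gene_b, bitscore=e.edge_bitscore)

    while True:
        candidates = []
        for comp in nx.connected_components(graph):
            if len(comp) <= 2:
                continue
            sub = graph.subgraph(comp)
            for a, b in nx.bridges(sub):
                a, b = sorted((a, b))
                candidates.append((sub[a][b]["bitscore"], a, b))
        if not candidates:
            break
        _, a, b = min(candidates)
        graph.remove_edge(a, b)

    families = []
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    width = max(4, len(str(len(comps))))
    for i, comp in enumerate(comps, start=1):
        families.append(ParalogFamily(f"fam{i:0{width}d}", frozenset(comp)))
    return families


def multi_copy_flags(families: Sequence[ParalogFamily]) -> dict[str, bool]:
    """Per-gene flag: True iff the gene's family has two or more members."""
    flags: dict[str, bool] = {}
    for fam in families:
        for gene in fam.members:
            flags[gene] = fam.size >= 2
    return flags
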