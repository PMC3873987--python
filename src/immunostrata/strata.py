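"""Phylostratigraphy: assign each gene the deepest stratum with a detectable homolog.

A detectable homolog is a blastp hit (already filtered at the upstream e-value
cutoff) whose alignment covers at least half of the shorter protein with at
least 30% positives; both boundaries are inclusive.  A gene's age is the
deepest stratum among the species contributing such hits — a single hit to a
non-arthropod outgroup makes a gene Metazoan no matter how gappy the pattern —
and a gene with no detectable homolog outside the focal species is Wasp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .de import STATUS_DOWN, STATUS_FILTERED, STATUS_NO_EXPRESSION, STATUS_UP
from .io_tables import BlastHit, SpeciesPanel, Stratum

__all__ = [
    "StratumAssignment",
    "is_detectable_homolog",
    "assign_stratum",
    "assign_all_strata",
    "stratum_table",
    "EXPRESSION_CLASSES",
]

MIN_COVERAGE = 0.5  # of the shorter protein, inclusive
MIN_PCT_POSITIVES = 30.0  # inclusive

EXPRESSION_CLASSES = ("induced", "repressed", "not_regulated")


@dataclass(frozen=True)
class StratumAssignment:
    gene_id: str
    stratum: Stratum
    supporting_species: frozenset[str]


def is_detectable_homolog(
    hit: BlastHit,
    min_coverage: float = MIN_COVERAGE,
    min_pct_positives: float = MIN_PCT_POSITIVES,
) -> bool:
    shorter = min(hit.query_len, hit.subject_len)
    return (
        hit.align_len >= min_coverage * shorter
        and hit.pct_positives >= min_pct_positives
    )


def assign_stratum(
    gene_id: str,
    gene_hits: Iterable[BlastHit],
    panel: SpeciesPanel,
) -> StratumAssignment:
    """Deepest stratum among the species with a detectable hit; Wasp if none.

    ``gene_hits`` must already be gene-level and filtered for detectability;
    hits to the focal species (self-hits) contribute nothing beyond Wasp.
    """
    supporting = set()
    deepest = Stratum.WASP
    for hit in gene_hits:
        stratum = panel.stratum_of(hit.subject_species)  # KeyError if unknown
        supporting.add(hit.subject_species)
        if stratum > deepest:
            deepest = stratum
    return StratumAssignment(gene_id, deepest, frozenset(supporting))


def assign_all_strata(
    gene_hits_by_species: Sequence[BlastHit],
    panel: SpeciesPanel,
    gene_universe: Iterable[str],
    min_coverage: float = MIN_COVERAGE,
    min_pct_positives: float = MIN_PCT_POSITIVES,
) -> dict[str, StratumAssignment]:
    """Assign a stratum to every gene in the universe.

    ``gene_hits_by_species`` are gene-level cross-species hits (query ids are
    gene ids); undetectable hits are ignored here, genes with no detectable
    hit are Wasp.
    """
    per_gene: dict[str, list[BlastHit]] = {g: [] for g in gene_universe}
    for hit in gene_hits_by_species:
        if not is_detectable_homolog(hit, min_coverage, min_pct_positives):
            continue
        if hit.query_protein not in per_gene:
            raise KeyError(f"hit for unknown gene {hit.query_protein!r}")
        per_gene[hit.query_protein].append(hit)
    return {g: assign_stratum(g, hits, panel) for g, hits in per_gene.items()}


def expression_class(status: str) -> str | None:
    """Collapse DE status to induced/repressed/not_regulated; None = not expressed."""
    if status == STATUS_UP:
        return "induced"
    if status == STATUS_DOWN:
        return "repressed"
    if status in (STATUS_NO_EXPRESSION, STATUS_FILTERED):
        return None
    return "not_regulated"


def stratum_table(
    assignments: Mapping[str, StratumAssignment],
    de_results: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate stratum × expression class over genes with significant expression.

    Genes filtered for low expression or with no expression are excluded, as
    are genes present in only one of the two inputs (with a warning recorded
    in the returned counts table's ``attrs``).  Returns (counts, row-wise
    proportions by expression class).
    """
    rows = []
    skipped = 0
    for gene, res in de_results.iterrows():
        cls = expression_class(res["status"])
        if cls is None:
            continue
        if gene not in assignments:
            skipped += 1
            continue
        rows.append((cls, assignments[gene].stratum.label()))
    skipped += sum(
        1
        for g in assignments
        if g not in de_results.index
    )
    frame = pd.DataFrame(rows, columns=["expression_class", "stratum"])
    stratum_order = [s.label() for s in Stratum]
    counts = (
        frame.groupby(["expression_class", "stratum"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=list(EXPRESSION_CLASSES), columns=stratum_order, fill_value=0)
    )
    counts.attrs["n_skipped_unmatched"] = skipped
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0, 1), axis=0)
    return counts, props
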