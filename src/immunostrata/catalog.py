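"""Homology-based immune catalog from three evidence sources.

Sources, in decreasing curation (and precedence) order: a curated
antimicrobial-peptide gene list; reciprocal best blastp hits (RBH) to
*Drosophila melanogaster* with annotation transfer from published immune gene
lists; and profile-HMM hits against a battery of immune family models, with a
Bonferroni-style e-value correction for the number of separate searches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_tables import BlastHit

__all__ = [
    "ImmuneAnnotation",
    "HmmHit",
    "IMMUNE_CLASSES",
    "SOURCE_PRECEDENCE",
    "reciprocal_best_hits",
    "transfer_dmel_annotation",
    "correct_and_filter_hmm",
    "merge_catalog",
]

IMMUNE_CLASSES = (
    "amp",
    "effector_other",
    "recognition",
    "signaling",
    "protease_or_inhibitor",
)

# most-curated evidence wins when a gene carries several
SOURCE_PRECEDENCE = ("amp_list", "rbh_dmel", "hmm")


@dataclass(frozen=True)
class ImmuneAnnotation:
    gene_id: str
    source: str  # one of SOURCE_PRECEDENCE
    immune_class: str  # one of IMMUNE_CLASSES
    detail: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCE_PRECEDENCE:
            raise ValueError(f"unknown annotation source {self.source!r}")
        if self.immune_class not in IMMUNE_CLASSES:
            raise ValueError(f"unknown immune class {self.immune_class!r}")


@dataclass(frozen=True)
class HmmHit:
    protein_id: str
    model_name: str
    evalue_raw: float
    evalue_corrected: float


def _best_hit_per_query(hits: Sequence[BlastHit]) -> dict[str, str | None]:
    """Unique best subject per query: min e-value, ties by max bitscore.

    A query whose top (e-value, bitscore) is shared by several subjects has no
    unique best hit and maps to None — a tied best disqualifies the pair.
    """
    by_query: dict[str, list[BlastHit]] = {}
    for hit in hits:
        by_query.setdefault(hit.query_protein, []).append(hit)
    best: dict[str, str | None] = {}
    for query, qhits in by_query.items():
        key = min((h.evalue, -h.bitscore) for h in qhits)
        top = sorted({h.subject_protein for h in qhits if (h.evalue, -h.bitscore) == key})
        best[query] = top[0] if len(top) == 1 else None
    return best


def reciprocal_best_hits(
    hits_nv_to_dm: Sequence[BlastHit],
    hits_dm_to_nv: Sequence[BlastHit],
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two gene-level hit tables.

    Pair (a, b) is reported iff b is a's unique best hit and a is b's unique
    best hit.  Both tables must already be collapsed to gene level.
    """
    fwd = _best_hit_per_query(hits_nv_to_dm)
    rev = _best_hit_per_query(hits_dm_to_nv)
    pairs = [
        (a, b)
        for a, b in fwd.items()
        if b is not None and rev.get(b) == a
    ]
    return sorted(pairs)


def transfer_dmel_annotation(
    rbh_pairs: Sequence[tuple[str, str]],
    dmel_immune_table: Mapping[str, str],
) -> list[ImmuneAnnotation]:
    """Assign each RBH-paired focal gene its fly partner's published immune class."""
    annotations = []
    for nv_gene, dm_gene in rbh_pairs:
        cls = dmel_immune_table.get(dm_gene)
        if cls is None:
            continue
        annotations.append(ImmuneAnnotation(nv_gene, "rbh_dmel", cls, detail=dm_gene))
    return annotations


def correct_and_filter_hmm(
    raw_hits: Sequence[tuple[str, str, float]],
    n_searches: int = 25,
) -> list[HmmHit]:
    """Correct profile-HMM e-values for multiple searches and filter.

    ``raw_hits`` are (protein_id, model_name, raw e-value) rows.  Each e-value
    is multiplied by ``n_searches`` (one hmmsearch per family model); hits
    whose corrected e-value exceeds 1 are dropped, and when several models hit
    the same protein only the smallest corrected e-value survives (ties by
    lexicographic model name).
    """
    if n_searches < 1:
        raise ValueError("n_searches must be >= 1")
    best: dict[str, HmmHit] = {}
    for protein, model, evalue in sorted(raw_hits, key=lambda r: (r[0], r[2], r[1])):
        if evalue < 0:
            raise ValueError(f"negative raw e-value for {protein}/{model}")
        corrected = evalue * n_searches
        if corrected > 1.0:
            continue
        old = best.get(protein)
        if old is None or (corrected, model) < (old.evalue_corrected, old.model_name):
            best[protein] = HmmHit(protein, model, evalue, corrected)
    return [best[p] for p in sorted(best)]


def hmm_annotations_from_hits(
    hmm_hits: Sequence[HmmHit],
    protein_to_gene: Mapping[str, str],
    model_class_map: Mapping[str, str],
) -> list[ImmuneAnnotation]:
    """Lift filtered protein-level HMM hits to gene-level immune annotations.

    When several isoforms of one gene are hit, the smallest corrected e-value
    decides which model names the gene (ties by lexicographic model name).
    """
    best: dict[str, HmmHit] = {}
    for hit in sorted(hmm_hits, key=lambda h: (h.evalue_corrected, h.model_name)):
        gene = protein_to_gene.get(hit.protein_id)
        if gene is None:
            raise KeyError(f"HMM hit for unknown protein {hit.protein_id!r}")
        best.setdefault(gene, hit)
    return [
        ImmuneAnnotation(gene, "hmm", model_class_map[hit.model_name], detail=hit.model_name)
        for gene, hit in sorted(best.items())
    ]


def merge_catalog(
    amp_genes: Iterable[str],
    rbh_annotations: Sequence[ImmuneAnnotation],
    hmm_annotations: Sequence[ImmuneAnnotation],
    gene_universe: Iterable[str],
) -> tuple[dict[str, ImmuneAnnotation], dict[str, int]]:
    """Merge the three evidence sources into one annotation per gene.

    Precedence amp_list > rbh_dmel > hmm resolves both the primary source and
    the class of multiply-annotated genes, so the catalog total is the size of
    the union and each gene is attributed to exactly one source in the
    summary.  The summary also reports the raw per-source gene totals, whose
    sum can exceed the catalog total when sources overlap.
    """
    universe = set(gene_universe)
    per_source: dict[str, dict[str, ImmuneAnnotation]] = {
        "amp_list": {g: ImmuneAnnotation(g, "amp_list", "amp") for g in amp_genes},
        "rbh_dmel": {a.gene_id: a for a in rbh_annotations},
        "hmm": {a.gene_id: a for a in hmm_annotations},
    }
    for source, annots in per_source.items():
        for ann in annots.values():
            if ann.gene_id not in universe:
                raise KeyError(f"{source} annotation for unknown gene {ann.gene_id!r}")
            if ann.source != source:
                raise ValueError(f"annotation {ann} listed under source {source!r}")

    final: dict[str, ImmuneAnnotation] = {}
    for source in SOURCE_PRECEDENCE:
        for gene, ann in per_source[source].items():
            final.setdefault(gene, ann)

    primary_counts = Counter(ann.source for ann in final.values())
    class_counts = Counter(ann.immune_class for ann in final.values())
    summary = {
        "total": len(final),
        **{f"primary_{s}": primary_counts.get(s, 0) for s in SOURCE_PRECEDENCE},
        **{f"raw_{s}": len(per_source[s]) for s in SOURCE_PRECEDENCE},
        **{f"class_{c}": class_counts.get(c, 0) for c in IMMUNE_CLASSES},
    }
    return final, summary
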