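"""Candidate novel-effector screen.

Known antimicrobial peptides are short, secreted and cationic, so induced
genes with no homology-based immune annotation are cascaded through exactly
those filters: (1) induced and non-immune; (2) protein under 300 amino acids
with a signal peptide; (3) no blastp hit in *D. melanogaster*; (4) positive
net charge.  Stage counts are nested by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .de import STATUS_UP
from .families import ParalogFamily, multi_copy_flags
from .io_tables import ProteinRecord, gene_lengths

__all__ = [
    "CandidateRecord",
    "STAGES",
    "net_charge",
    "screen",
    "novelty_summary",
]

STAGES = ("induced_nonimmune", "short_secreted", "no_dmel_hit", "charged_candidate")

DEFAULT_MAX_LEN = 300  # strict: candidate proteins are < 300 aa


@dataclass(frozen=True)
class CandidateRecord:
    gene_id: str
    length_aa: int
    has_signal: bool
    has_dmel_hit: bool
    net_charge: int
    stage_reached: str

    def __post_init__(self) -> None:
        if self.stage_reached not in STAGES:
            raise ValueError(f"unknown stage {self.stage_reached!r}")


def net_charge(sequence: str, include_histidine: bool = False) -> int:
    """Net charge at neutral pH: (#K + #R) − (#D + #E); termini ignored.

    Histidine is mostly uncharged at pH 7 and is excluded by default; pass
    ``include_histidine=True`` to count it as +1.  X residues are ignored.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    charge = seq.count("K") + seq.count("R") - seq.count("D") - seq.count("E")
    if include_histidine:
        charge += seq.count("H")
    return charge


def _gene_charges(proteins: Sequence[ProteinRecord], include_histidine: bool) -> dict[str, int]:
    # charge of the longest isoform (the same isoform that defines gene length)
    longest: dict[str, ProteinRecord] = {}
    for p in proteins:
        if p.gene_id not in longest or p.length_aa > longest[p.gene_id].length_aa:
            longest[p.gene_id] = p
    return {g: net_charge(p.sequence, include_histidine) for g, p in longest.items()}


def screen(
    de_results: pd.DataFrame,
    immune_genes: set[str],
    proteins: Sequence[ProteinRecord],
    signal_flags: Mapping[str, bool],
    dmel_hit_genes: set[str],
    max_len: int = DEFAULT_MAX_LEN,
    include_histidine: bool = False,
) -> tuple[list[CandidateRecord], dict[str, int]]:
    """Run the four-stage candidate cascade over induced genes.

    ``dmel_hit_genes`` is the set of genes with *any* fly blastp hit at the
    upstream e-value cutoff (not merely an RBH).  Gene protein length is the
    longest isoform's; the signal flag is the any-isoform OR.  Returns the
    per-gene records (one per stage-1 gene) and nested per-stage counts.
    """
    lengths = gene_lengths(proteins)
    charges = _gene_charges(proteins, include_histidine)
    induced = [g for g, r in de_results.iterrows() if r["status"] == STATUS_UP]
    stage1 = [g for g in induced if g not in immune_genes]
    missing = [g for g in stage1 if g not in lengths]
    if missing:
        raise KeyError(f"no protein sequence for induced genes: {missing}")

    records = []
    for gene in stage1:
        length = lengths[gene]
        signal = bool(signal_flags.get(gene, False))
        has_dmel = gene in dmel_hit_genes
        charge = charges[gene]
        stage = "induced_nonimmune"
        if length < max_len and signal:
            stage = "short_secreted"
            if not has_dmel:
                stage = "no_dmel_hit"
                if charge > 0:
                    stage = "charged_candidate"
        records.append(CandidateRecord(gene, length, signal, has_dmel, charge, stage))

    stage_rank = {s: i for i, s in enumerate(STAGES)}
    counts = {
        s: sum(1 for r in records if stage_rank[r.stage_reached] >= i)
        for i, s in enumerate(STAGES)
    }
    return records, counts


def novelty_summary(
    de_results: pd.DataFrame,
    immune_genes: set[str],
    families: Sequence[ParalogFamily],
    proteins: Sequence[ProteinRecord],
    signal_flags: Mapping[str, bool],
    max_len: int = DEFAULT_MAX_LEN,
) -> dict[str, float]:
    """Fraction of induced non-immune genes with at least one AMP-like property.

    Properties: membership in a multi-gene family, protein shorter than
    ``max_len`` amino acids, or a signal peptide.
    """
    lengths = gene_lengths(proteins)
    multi = multi_copy_flags(families)
    denom_genes = [
        g
        for g, r in de_results.iterrows()
        if r["status"] == STATUS_UP and g not in immune_genes
    ]
    if not denom_genes:
        raise ValueError("no induced non-immune genes; fraction undefined")
    numer = sum(
        1
        for g in denom_genes
        if multi.get(g, False)
        or lengths.get(g, max_len) < max_len
        or signal_flags.get(g, False)
    )
    return {
        "numerator": numer,
        "denominator": len(denom_genes),
        "fraction": numer / len(denom_genes),
    }
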