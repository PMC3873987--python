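"""Readers/writers for the pipeline's on-disk tables and the isoform→gene collapse.

All formats are plain tab-separated text.  Protein-vs-protein hit tables use the
standard 12-column blast tabular layout extended with three extra columns
(``ppos qlen slen``): the homology-detectability and paralog rules downstream are
stated on percent positives and on the shorter/longer protein length, which the
12-column default does not carry.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Stratum",
    "ProteinRecord",
    "BlastHit",
    "CountRecord",
    "SignalPeptideCall",
    "SpeciesPanel",
    "read_blast_table",
    "write_blast_table",
    "read_counts",
    "write_counts",
    "read_signal_calls",
    "write_signal_calls",
    "read_species_panel",
    "write_species_panel",
    "read_gene_list",
    "write_gene_list",
    "read_proteins",
    "write_proteins",
    "collapse_isoform_hits",
    "aggregate_signal_calls",
]

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


class Stratum(enum.IntEnum):
    """Phylogenetic age strata, ordered shallow → deep (larger = older)."""

    WASP = 0
    HYMENOPTERA = 1
    INSECT = 2
    ARTHROPOD = 3
    METAZOAN = 4

    @classmethod
    def from_name(cls, name: str) -> "Stratum":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown stratum name: {name!r}") from None

    def label(self) -> str:
        return self.name.capitalize()


@dataclass(frozen=True)
class ProteinRecord:
    """One protein isoform of a gene model."""

    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: non-amino-acid characters {sorted(bad)}"
            )
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BlastHit:
    """A single directional protein-vs-protein hit (extended tabular row)."""

    query_protein: str
    subject_protein: str
    subject_species: str
    evalue: float
    bitscore: float
    pct_positives: float
    align_len: int
    query_len: int
    subject_len: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_protein}")
        if self.bitscore <= 0:
            raise ValueError(f"non-positive bitscore for {self.query_protein}")
        if not 0 <= self.pct_positives <= 100:
            raise ValueError(f"pct_positives outside [0, 100] for {self.query_protein}")
        if self.align_len <= 0 or self.query_len <= 0 or self.subject_len <= 0:
            raise ValueError(f"non-positive length field for {self.query_protein}")
        if self.align_len > self.query_len + self.subject_len:
            raise ValueError(
                f"alignment of {self.query_protein} vs {self.subject_protein} longer "
                "than both sequences combined"
            )


@dataclass(frozen=True)
class CountRecord:
    """Raw read counts for one gene in the two libraries."""

    gene_id: str
    count_infected: int
    count_uninfected: int

    def __post_init__(self) -> None:
        if self.count_infected < 0 or self.count_uninfected < 0:
            raise ValueError(f"negative count for gene {self.gene_id}")


@dataclass(frozen=True)
class SignalPeptideCall:
    protein_id: str
    has_signal: bool


@dataclass
class SpeciesPanel:
    """The cross-species blast panel: species → stratum, plus Hymenoptera membership.

    The focal species must map to the Wasp stratum; every other species carries
    the deepest stratum its clade represents relative to the focal lineage.
    """

    focal_species: str
    strata: dict[str, Stratum]
    is_hymenopteran: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.focal_species not in self.strata:
            raise ValueError(f"focal species {self.focal_species!r} missing from panel")
        if self.strata[self.focal_species] != Stratum.WASP:
            raise ValueError("the focal species must map to the Wasp stratum")
        for sp in self.strata:
            self.is_hymenopteran.setdefault(sp, self.strata[sp] <= Stratum.HYMENOPTERA)

    def stratum_of(self, species: str) -> Stratum:
        try:
            return self.strata[species]
        except KeyError:
            raise KeyError(f"species {species!r} not in panel") from None

    @property
    def species(self) -> list[str]:
        return sorted(self.strata)

    def non_hymenopteran_species(self) -> set[str]:
        return {sp for sp, hym in self.is_hymenopteran.items() if not hym}


# ---------------------------------------------------------------------------
# Blast hit tables (extended 15-column tabular)
# ---------------------------------------------------------------------------

_BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore ppos qlen slen"
).split()


def read_blast_table(path: str | Path, subject_species: str = "") -> list[BlastHit]:
    """Parse an extended blast tabular file (15 tab-separated columns).

    ``subject_species`` labels every hit in the file (one file per target
    proteome).  An empty file yields an empty list; a malformed row raises
    ``ValueError`` naming its line number.
    """
    path = Path(path)
    hits: list[BlastHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_BLAST_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_BLAST_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = BlastHit(
                    query_protein=fields[0],
                    subject_protein=fields[1],
                    subject_species=subject_species,
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    pct_positives=float(fields[12]),
                    align_len=int(fields[3]),
                    query_len=int(fields[13]),
                    subject_len=int(fields[14]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            hits.append(hit)
    return hits


def write_blast_table(hits: Iterable[BlastHit], path: str | Path) -> None:
    """Write hits in the extended tabular layout.

    Only the fields the pipeline consumes are meaningful; the positional
    columns are filled with 1-based placeholders spanning the alignment so the
    row round-trips through :func:`read_blast_table` bit-exactly on the
    consumed fields.
    """
    path = Path(path)
    with path.open("w") as fh:
        for h in hits:
            row = [
                h.query_protein,
                h.subject_protein,
                repr(h.pct_positives),
                str(h.align_len),
                "0",
                "0",
                "1",
                str(h.align_len),
                "1",
                str(h.align_len),
                repr(h.evalue),
                repr(h.bitscore),
                repr(h.pct_positives),
                str(h.query_len),
                str(h.subject_len),
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Simple two/three-column tables
# ---------------------------------------------------------------------------


def _read_tsv_rows(path: str | Path, ncols: int, header: str | None) -> list[list[str]]:
    path = Path(path)
    rows: list[list[str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is not None and lineno == 1 and fields[0] == header:
                continue
            if len(fields) != ncols:
                raise ValueError(f"{path}:{lineno}: expected {ncols} columns")
            rows.append(fields)
    return rows


def read_counts(path: str | Path) -> list[CountRecord]:
    """Read a counts TSV: gene_id, infected count, uninfected count."""
    records = []
    for gene, inf, unf in _read_tsv_rows(path, 3, header="gene_id"):
        try:
            records.append(CountRecord(gene, int(inf), int(unf)))
        except ValueError as exc:
            raise ValueError(f"{path}: bad counts for gene {gene}: {exc}") from None
    return records


def write_counts(records: Iterable[CountRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tcount_infected\tcount_uninfected\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.count_infected}\t{r.count_uninfected}\n")


def read_signal_calls(path: str | Path) -> list[SignalPeptideCall]:
    calls = []
    seen: set[str] = set()
    for pid, flag in _read_tsv_rows(path, 2, header="protein_id"):
        if pid in seen:
            raise ValueError(f"{path}: duplicate signal-peptide call for {pid}")
        seen.add(pid)
        calls.append(SignalPeptideCall(pid, flag.strip().lower() in {"1", "true", "yes"}))
    return calls


def write_signal_calls(calls: Iterable[SignalPeptideCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein_id\thas_signal\n")
        for c in calls:
            fh.write(f"{c.protein_id}\t{'true' if c.has_signal else 'false'}\n")


def read_species_panel(path: str | Path, focal_species: str | None = None) -> SpeciesPanel:
    """Read a panel TSV: species, stratum, is_hymenopteran.

    If ``focal_species`` is not given, the (unique) species at the Wasp stratum
    is taken as focal.
    """
    strata: dict[str, Stratum] = {}
    hym: dict[str, bool] = {}
    for sp, stratum, is_hym in _read_tsv_rows(path, 3, header="species"):
        if sp in strata:
            raise ValueError(f"{path}: duplicate species {sp}")
        strata[sp] = Stratum.from_name(stratum)
        hym[sp] = is_hym.strip().lower() in {"1", "true", "yes"}
    if focal_species is None:
        wasps = [sp for sp, st in strata.items() if st == Stratum.WASP]
        if len(wasps) != 1:
            raise ValueError(
                f"{path}: cannot infer focal species ({len(wasps)} Wasp-stratum rows)"
            )
        focal_species = wasps[0]
    return SpeciesPanel(focal_species, strata, hym)


def write_species_panel(panel: SpeciesPanel, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("species\tstratum\tis_hymenopteran\n")
        for sp in panel.species:
            fh.write(
                f"{sp}\t{panel.strata[sp].label()}\t"
                f"{'true' if panel.is_hymenopteran[sp] else 'false'}\n"
            )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-column gene list (e.g. the curated AMP gene list)."""
    return [row[0] for row in _read_tsv_rows(path, 1, header="gene_id")]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\n")
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# Proteins: FASTA + isoform→gene sidecar TSV
# ---------------------------------------------------------------------------


def read_proteins(fasta_path: str | Path, isoform_map_path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA plus its two-column isoform→gene sidecar TSV."""
    gene_of: dict[str, str] = {}
    for pid, gid in _read_tsv_rows(isoform_map_path, 2, header="protein_id"):
        if pid in gene_of:
            raise ValueError(f"{isoform_map_path}: protein {pid} mapped twice")
        gene_of[pid] = gid
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in gene_of:
            raise ValueError(f"{fasta_path}: protein {rec.id} missing from isoform map")
        records.append(ProteinRecord(rec.id, gene_of[rec.id], str(rec.seq).upper()))
    return records


def write_proteins(
    proteins: Iterable[ProteinRecord],
    fasta_path: str | Path,
    isoform_map_path: str | Path,
) -> None:
    proteins = list(proteins)
    seqs = [SeqRecord(Seq(p.sequence), id=p.protein_id, description="") for p in proteins]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    with Path(isoform_map_path).open("w") as fh:
        fh.write("protein_id\tgene_id\n")
        for p in proteins:
            fh.write(f"{p.protein_id}\t{p.gene_id}\n")


# ---------------------------------------------------------------------------
# Isoform-level → gene-level operations
# ---------------------------------------------------------------------------


def protein_to_gene_map(proteins: Iterable[ProteinRecord]) -> dict[str, str]:
    return {p.protein_id: p.gene_id for p in proteins}


def gene_lengths(proteins: Iterable[ProteinRecord]) -> dict[str, int]:
    """Per-gene protein length = length of the longest isoform."""
    lengths: dict[str, int] = {}
    for p in proteins:
        lengths[p.gene_id] = max(lengths.get(p.gene_id, 0), p.length_aa)
    return lengths


def _better(hit: BlastHit, incumbent: BlastHit) -> bool:
    """Lower e-value wins; ties by higher bitscore, then lexicographic subject id."""
    key_new = (hit.evalue, -hit.bitscore, hit.subject_protein)
    key_old = (incumbent.evalue, -incumbent.bitscore, incumbent.subject_protein)
    return key_new < key_old


def collapse_isoform_hits(
    hits: Sequence[BlastHit],
    query_map: Mapping[str, str],
    subject_map: Mapping[str, str] | None = None,
) -> list[BlastHit]:
    """Collapse isoform-level hits to gene level, keeping the lowest-e-value hit.

    ``query_map`` maps query protein ids to gene ids.  If ``subject_map`` is
    given, subjects are also collapsed to genes and the retained hit per
    (query gene, subject gene) is the minimum-e-value one; otherwise hits are
    grouped per (query gene, subject protein).  Ties break by higher bitscore,
    then lexicographically smaller subject id, so the result is independent of
    input order.
    """
    best: dict[tuple[str, str], BlastHit] = {}
    order: list[tuple[str, str]] = []
    for hit in hits:
        if hit.query_protein not in query_map:
            raise KeyError(f"hit query {hit.query_protein!r} not in the protein map")
        qgene = query_map[hit.query_protein]
        if subject_map is not None:
            if hit.subject_protein not in subject_map:
                raise KeyError(f"hit subject {hit.subject_protein!r} not in the subject map")
            skey = subject_map[hit.subject_protein]
        else:
            skey = hit.subject_protein
        key = (qgene, skey)
        if key not in best:
            best[key] = hit
            order.append(key)
        elif _better(hit, best[key]):
            best[key] = hit
    return [best[k] for k in sorted(order)]


def to_gene_level(
    hits: Sequence[BlastHit],
    query_map: Mapping[str, str],
    subject_map: Mapping[str, str] | None = None,
) -> list[BlastHit]:
    """Collapse isoform hits and rewrite ids so query (and optionally subject)
    fields carry gene ids.  The numeric fields of the retained hit are kept."""
    import dataclasses

    collapsed = collapse_isoform_hits(hits, query_map, subject_map)
    out = []
    for hit in collapsed:
        repl: dict[str, str] = {"query_protein": query_map[hit.query_protein]}
        if subject_map is not None:
            repl["subject_protein"] = subject_map[hit.subject_protein]
        out.append(dataclasses.replace(hit, **repl))
    return out


def aggregate_signal_calls(
    calls: Sequence[SignalPeptideCall],
    proteins: Sequence[ProteinRecord],
) -> dict[str, bool]:
    """Per-gene signal-peptide flag: logical OR over the gene's isoform calls.

    A gene none of whose isoforms appears in ``calls`` is False (no evidence).
    """
    known = protein_to_gene_map(proteins)
    flags: dict[str, bool] = {g: False for g in known.values()}
    for call in calls:
        gene = known.get(call.protein_id)
        if gene is None:
            raise KeyError(f"signal call for unknown protein {call.protein_id!r}")
        flags[gene] = flags[gene] or call.has_signal
    return flags
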