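"""Synthetic-data generator with planted ground truth.

Emulates every input the pipeline consumes — a two-library count table,
a proteome with isoforms, cross-species / self / fly blastp hit tables,
profile-HMM hits, signal-peptide calls, the curated AMP list and the species
panel — from a single seeded configuration, together with a truth table
(planted fold changes, ages, families, immune classes, effector labels) so
that every analysis stage can be checked for recovery.

Defaults mirror the study conditions this pipeline targets: ~24 thousand gene
models, ~1.3% induced and ~0.4% repressed genes, ~12% of genes with no
expression, a median expressed-gene abundance of a handful of normalized
counts, ~2% immune genes split across the three evidence sources, and a
five-stratum age distribution dominated by deeply conserved genes.  The two
libraries emulate pools of many individuals sequenced once each, so the NB
dispersion default is small (technical/pool scale), not the
biological-replicate scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .io_tables import (
    BlastHit,
    CountRecord,
    ProteinRecord,
    SignalPeptideCall,
    SpeciesPanel,
    Stratum,
    write_blast_table,
    write_counts,
    write_gene_list,
    write_proteins,
    write_signal_calls,
    write_species_panel,
)

__all__ = [
    "GeneratorConfig",
    "TruthSet",
    "SyntheticInputs",
    "default_panel",
    "HMM_MODEL_CLASSES",
    "generate_truth",
    "generate_counts",
    "generate_hit_tables",
    "generate_all",
    "write_inputs",
]

STRATA = [s.label() for s in Stratum]

# 25 immune family profile-HMM models and the class each confers
HMM_MODEL_CLASSES: dict[str, str] = {
    "defensin": "amp",
    "abaecin": "amp",
    "hymenoptaecin": "amp",
    "attacin": "amp",
    "cecropin": "amp",
    "PGRP": "recognition",
    "TEP": "recognition",
    "GNBP": "recognition",
    "nimrod": "recognition",
    "ctl_lectin": "recognition",
    "galectin": "recognition",
    "scavenger_SRCR": "recognition",
    "toll": "signaling",
    "spatzle": "signaling",
    "myd88": "signaling",
    "imd": "signaling",
    "relish": "signaling",
    "stat": "signaling",
    "cactus": "signaling",
    "pelle": "signaling",
    "lysozyme": "effector_other",
    "transferrin": "effector_other",
    "peroxidase": "effector_other",
    "PPO": "effector_other",
    "clip_serine_protease": "protease_or_inhibitor",
}

_NEUTRAL_RESIDUES = np.array(list("ACFGILMNPQSTVWY"))


class GeneratorConfig(BaseModel):
    """All planted rates and distributions; the seed is mandatory."""

    seed: int
    n_genes: int = 24389
    fraction_induced: float = 0.0129
    fraction_repressed: float = 0.0043
    fraction_zero_expression: float = 0.121
    # |log2fc| magnitudes are log-normal with this mean; sdlog 0 plants the
    # mean exactly for every regulated gene
    lfc_mean: float = 2.0
    lfc_sdlog: float = 0.8
    # NB dispersion of the two pooled libraries (variance = mu + alpha*mu^2)
    dispersion: float = 0.02
    # baseline mean normalized counts, log-normal (median ~7 expressed counts)
    baseline_meanlog: float = math.log(7.0)
    baseline_sdlog: float = 2.0
    size_factor_infected: float = 1.16
    size_factor_uninfected: float = 0.86
    # age distribution over the five strata, shallow -> deep
    age_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "Wasp": 0.17,
            "Hymenoptera": 0.08,
            "Insect": 0.08,
            "Arthropod": 0.07,
            "Metazoan": 0.60,
        }
    )
    fraction_immune: float = 0.0204
    # split of immune genes across evidence sources (amp_list, rbh_dmel, hmm)
    immune_source_probs: tuple[float, float, float] = (0.064, 0.213, 0.723)
    # induction-probability multipliers linking induction to immunity and youth
    immune_induction_multiplier: float = 4.7
    youth_induction_multiplier: float = 2.2
    # geometric family-size parameter; fraction of genes in multi-gene
    # families is 1 - p^2 (~0.18 at the default)
    family_geometric_p: float = 0.906
    # induced genes are this much likelier to occupy a multi-family slot
    induced_multicopy_weight: float = 3.5
    signal_prob_amp: float = 0.912
    signal_prob_induced_nonimmune: float = 0.42
    signal_prob_background: float = 0.16
    length_meanlog_induced: float = 5.578  # P(length < 300) ~ 0.57
    length_meanlog_background: float = 5.845  # P(length < 300) ~ 0.42
    length_meanlog_amp: float = 4.70
    length_sdlog: float = 0.7
    prob_second_isoform: float = 0.3
    prob_dmel_hit_given_deep: float = 0.85
    max_supporting_species: int = 4
    decoys: bool = True

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for name in (
            "fraction_induced",
            "fraction_repressed",
            "fraction_zero_expression",
            "fraction_immune",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fraction_induced + self.fraction_repressed > 1:
            raise ValueError("induced + repressed fractions exceed 1")
        if abs(sum(self.age_probs.values()) - 1) > 1e-9:
            raise ValueError("age_probs must sum to 1")
        if set(self.age_probs) != set(STRATA):
            raise ValueError(f"age_probs must cover exactly the strata {STRATA}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 < self.family_geometric_p <= 1:
            raise ValueError("family_geometric_p must lie in (0, 1]")
        return self


@dataclass
class TruthSet:
    """Planted per-gene ground truth, aligned with every generated table."""

    genes: pd.DataFrame  # indexed by gene_id

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthSet":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df)

    def family_partition(self) -> list[frozenset[str]]:
        return [
            frozenset(members.index)
            for _, members in self.genes.groupby("family_id")
        ]


@dataclass
class SyntheticInputs:
    """All generated pipeline inputs, in memory."""

    proteins: list[ProteinRecord]
    signal_calls: list[SignalPeptideCall]
    species_hits: dict[str, list[BlastHit]]  # per panel species (protein-level)
    self_hits: list[BlastHit]  # focal-vs-focal (protein-level)
    dmel_to_nv_hits: list[BlastHit]  # gene-level fly queries, focal protein subjects
    hmm_hits_raw: list[tuple[str, str, float]]
    amp_genes: list[str]
    dmel_immune_table: dict[str, str]
    model_class_map: dict[str, str] = field(default_factory=lambda: dict(HMM_MODEL_CLASSES))


def default_panel(focal_species: str = "Nasonia_vitripennis") -> SpeciesPanel:
    """A 30-genome panel: 12 Hymenoptera, 11 other insects (fly included),
    2 non-insect arthropods and 5 non-arthropod outgroups."""
    strata: dict[str, Stratum] = {focal_species: Stratum.WASP}
    hymenoptera = [
        "Apis_mellifera",
        "Bombus_terrestris",
        "Megachile_rotundata",
        "Camponotus_floridanus",
        "Harpegnathos_saltator",
        "Linepithema_humile",
        "Pogonomyrmex_barbatus",
        "Solenopsis_invicta",
        "Atta_cephalotes",
        "Acromyrmex_echinatior",
        "Cerapachys_biroi",
        "Trichogramma_pretiosum",
    ]
    insects = [
        "Drosophila_melanogaster",
        "Drosophila_pseudoobscura",
        "Anopheles_gambiae",
        "Aedes_aegypti",
        "Culex_quinquefasciatus",
        "Glossina_morsitans",
        "Tribolium_castaneum",
        "Bombyx_mori",
        "Acyrthosiphon_pisum",
        "Pediculus_humanus",
        "Zootermopsis_nevadensis",
    ]
    arthropods = ["Daphnia_pulex", "Ixodes_scapularis"]
    outgroups = [
        "Caenorhabditis_elegans",
        "Homo_sapiens",
        "Mus_musculus",
        "Danio_rerio",
        "Nematostella_vectensis",
    ]
    for sp in hymenoptera:
        strata[sp] = Stratum.HYMENOPTERA
    for sp in insects:
        strata[sp] = Stratum.INSECT
    for sp in arthropods:
        strata[sp] = Stratum.ARTHROPOD
    for sp in outgroups:
        strata[sp] = Stratum.METAZOAN
    hym_flags = {sp: strata[sp] <= Stratum.HYMENOPTERA for sp in strata}
    return SpeciesPanel(focal_species, strata, hym_flags)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------


def generate_truth(config: GeneratorConfig) -> TruthSet:
    """Plant the per-gene ground truth (deterministic given the seed).

    Induction probability is multiplied up for planted-immune and
    planted-young genes; repression, zero-expression, family membership,
    protein lengths, signal peptides, charges and fly-hit status all follow,
    in that order, from dedicated substreams of the master seed.
    """
    rng = _streams(config.seed, 6)[0]
    n = config.n_genes
    width = max(5, len(str(n)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]

    ages = rng.choice(STRATA, size=n, p=[config.age_probs[s] for s in STRATA])
    young = np.isin(ages, ["Wasp", "Hymenoptera"])
    deep = np.isin(ages, ["Insect", "Arthropod", "Metazoan"])

    # immune genes and their evidence sources; RBH-source genes need a fly
    # ortholog so they are drawn from deep-age genes
    n_immune = int(round(config.fraction_immune * n))
    src_probs = np.array(config.immune_source_probs)
    src_counts = np.round(src_probs / src_probs.sum() * n_immune).astype(int)
    src_counts[2] = n_immune - src_counts[0] - src_counts[1]
    immune_source = np.array([""] * n, dtype=object)
    deep_idx = np.flatnonzero(deep)
    rbh_idx = rng.choice(deep_idx, size=src_counts[1], replace=False)
    immune_source[rbh_idx] = "rbh_dmel"
    remaining = np.flatnonzero(immune_source == "")
    other_idx = rng.choice(remaining, size=src_counts[0] + src_counts[2], replace=False)
    immune_source[other_idx[: src_counts[0]]] = "amp_list"
    immune_source[other_idx[src_counts[0] :]] = "hmm"
    is_immune = immune_source != ""

    immune_class = np.array([""] * n, dtype=object)
    immune_class[immune_source == "amp_list"] = "amp"
    other_classes = ["recognition", "signaling", "effector_other", "protease_or_inhibitor"]
    for idx in np.flatnonzero(np.isin(immune_source, ["rbh_dmel", "hmm"])):
        immune_class[idx] = rng.choice(other_classes, p=[0.25, 0.25, 0.15, 0.35])
    # some HMM-found genes are AMPs too
    hmm_idx = np.flatnonzero(immune_source == "hmm")
    amp_like = rng.random(hmm_idx.size) < 0.10
    immune_class[hmm_idx[amp_like]] = "amp"

    # induction with planted enrichment toward immunity and youth
    weight = np.ones(n)
    weight[is_immune] *= config.immune_induction_multiplier
    weight[young] *= config.youth_induction_multiplier
    p_ind = np.minimum(1.0, weight * (config.fraction_induced * n / weight.sum()))
    induced = rng.random(n) < p_ind
    repressed = (~induced) & (rng.random(n) < config.fraction_repressed / max(1e-12, 1 - config.fraction_induced))

    # zero-expression genes (never the regulated ones)
    regulated = induced | repressed
    p_zero = config.fraction_zero_expression / max(1e-12, 1 - regulated.mean())
    zero = (~regulated) & (rng.random(n) < p_zero)

    # planted log2 fold changes
    lfc = np.zeros(n)
    n_reg = int(regulated.sum())
    if config.lfc_sdlog > 0:
        mags = rng.lognormal(
            math.log(config.lfc_mean) - config.lfc_sdlog**2 / 2,
            config.lfc_sdlog,
            size=n_reg,
        )
    else:
        mags = np.full(n_reg, config.lfc_mean)
    lfc[regulated] = mags
    lfc[repressed] *= -1

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=n)
    baseline[zero] = 0.0

    # family partition: geometric sizes; induced genes preferentially fill
    # multi-gene-family slots
    sizes: list[int] = []
    covered = 0
    while covered < n:
        size = min(int(rng.geometric(config.family_geometric_p)), n - covered)
        sizes.append(size)
        covered += size
    slots = np.repeat(np.arange(len(sizes)), sizes)
    fam_sizes = np.array(sizes)[slots]  # family size of each slot
    w = np.ones(n)
    w[induced] = config.induced_multicopy_weight
    # weighted permutation via the Gumbel-max trick (O(n log n), deterministic)
    order = np.argsort(-(np.log(w) + rng.gumbel(size=n)), kind="stable")
    # genes drawn first occupy multi-family slots (slots sorted by size desc)
    slot_order = np.argsort(-fam_sizes, kind="stable")
    family_idx = np.empty(n, dtype=int)
    family_idx[order] = slots[slot_order]
    fam_width = max(5, len(str(len(sizes))))
    family_id = np.array([f"tfam{j:0{fam_width}d}" for j in family_idx], dtype=object)

    # protein lengths: AMPs short, induced non-immune shortish, young genes shorter
    meanlog = np.full(n, config.length_meanlog_background)
    meanlog[induced & ~is_immune] = config.length_meanlog_induced
    meanlog[immune_class == "amp"] = config.length_meanlog_amp
    meanlog[ages == "Wasp"] -= 0.30
    meanlog[ages == "Hymenoptera"] -= 0.15
    length = np.maximum(
        30, np.round(rng.lognormal(meanlog, config.length_sdlog)).astype(int)
    )

    p_signal = np.full(n, config.signal_prob_background)
    p_signal[induced & ~is_immune] = config.signal_prob_induced_nonimmune
    p_signal[immune_class == "amp"] = config.signal_prob_amp
    has_signal = rng.random(n) < p_signal

    charge = np.round(rng.normal(-3.0, 4.0, size=n)).astype(int)
    cationic = (immune_class == "amp") | (induced & ~is_immune)
    charge[cationic] = np.round(rng.normal(2.0, 3.0, size=int(cationic.sum()))).astype(int)
    # keep planted charges realizable within the protein length
    charge = np.clip(charge, -(length // 4), length // 4)

    has_dmel = deep & (rng.random(n) < config.prob_dmel_hit_given_deep)
    has_dmel[immune_source == "rbh_dmel"] = True

    n_isoforms = 1 + (rng.random(n) < config.prob_second_isoform).astype(int)

    is_novel_amp = (
        induced
        & ~is_immune
        & (length < 300)
        & has_signal
        & ~has_dmel
        & (charge > 0)
    )

    genes = pd.DataFrame(
        {
            "lfc": lfc,
            "baseline": baseline,
            "dispersion": config.dispersion,
            "zero_expression": zero,
            "age": ages,
            "family_id": family_id,
            "immune_source": immune_source,
            "immune_class": immune_class,
            "length_aa": length,
            "n_isoforms": n_isoforms,
            "has_signal": has_signal,
            "net_charge": charge,
            "has_dmel_hit": has_dmel,
            "induced": induced,
            "repressed": repressed,
            "is_novel_amp": is_novel_amp,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return TruthSet(genes)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def generate_counts(truth: TruthSet, config: GeneratorConfig) -> list[CountRecord]:
    """NB counts with mean s_j * q_i * 2^(±lfc/2); planted-zero genes emit (0, 0)."""
    rng = _streams(config.seed, 6)[1]
    g = truth.genes
    q = g["baseline"].to_numpy(float)
    lfc = g["lfc"].to_numpy(float)
    mu_inf = config.size_factor_infected * q * np.exp2(lfc / 2.0)
    mu_unf = config.size_factor_uninfected * q * np.exp2(-lfc / 2.0)
    alpha = g["dispersion"].to_numpy(float)

    def draw(mu: np.ndarray) -> np.ndarray:
        k = np.zeros(mu.size, dtype=int)
        pos = mu > 0
        a = alpha[pos]
        m = mu[pos]
        out = np.empty(m.size, dtype=int)
        nbin = a > 0
        if nbin.any():
            r = 1.0 / a[nbin]
            p = r / (r + m[nbin])
            out[nbin] = rng.negative_binomial(r, p)
        if (~nbin).any():
            out[~nbin] = rng.poisson(m[~nbin])
        k[pos] = out
        return k

    k_inf = draw(mu_inf)
    k_unf = draw(mu_unf)
    return [
        CountRecord(gene, int(ki), int(ku))
        for gene, ki, ku in zip(g.index, k_inf, k_unf)
    ]


# ---------------------------------------------------------------------------
# Hit tables, proteome and the rest of the inputs
# ---------------------------------------------------------------------------


def _make_sequence(rng: np.random.Generator, length: int, charge: int) -> str:
    """Amino-acid sequence of the given length whose (K+R)-(D+E) equals ``charge``."""
    extra = int(rng.integers(0, 4))
    n_pos = max(charge, 0) + extra
    n_neg = n_pos - charge
    while n_pos + n_neg > length:  # tight sequences: shed the padding pairs
        n_pos -= 1
        n_neg -= 1
    pos_res = rng.choice(np.array(["K", "R"]), size=n_pos)
    neg_res = rng.choice(np.array(["D", "E"]), size=n_neg)
    rest = rng.choice(_NEUTRAL_RESIDUES, size=length - n_pos - n_neg)
    seq = np.concatenate([pos_res, neg_res, rest])
    return "".join(seq[rng.permutation(length)])


def _detectable_hit(
    rng: np.random.Generator,
    query: str,
    subject: str,
    species: str,
    qlen: int,
    evalue: float,
) -> BlastHit:
    slen = max(30, int(round(qlen * rng.uniform(0.8, 1.25))))
    shorter = min(qlen, slen)
    align = max(1, int(math.ceil(rng.uniform(0.55, 0.95) * shorter)))
    return BlastHit(
        query_protein=query,
        subject_protein=subject,
        subject_species=species,
        evalue=evalue,
        bitscore=round(float(rng.uniform(60, 400)), 1),
        pct_positives=round(float(rng.uniform(35, 95)), 2),
        align_len=align,
        query_len=qlen,
        subject_len=slen,
    )


def _decoy_hit(
    rng: np.random.Generator,
    query: str,
    subject: str,
    species: str,
    qlen: int,
) -> BlastHit:
    """A genuine blastp hit that fails detectability (coverage or positives)."""
    slen = max(30, int(round(qlen * rng.uniform(0.8, 1.25))))
    shorter = min(qlen, slen)
    if rng.random() < 0.5:  # sub-threshold coverage
        align = max(1, int(math.floor(rng.uniform(0.10, 0.45) * shorter)))
        positives = round(float(rng.uniform(35, 95)), 2)
    else:  # sub-threshold positives
        align = max(1, int(math.ceil(rng.uniform(0.55, 0.95) * shorter)))
        positives = round(float(rng.uniform(10, 29)), 2)
    return BlastHit(
        query_protein=query,
        subject_protein=subject,
        subject_species=species,
        evalue=10.0 ** -rng.uniform(4, 30),
        bitscore=round(float(rng.uniform(40, 120)), 1),
        pct_positives=positives,
        align_len=align,
        query_len=qlen,
        subject_len=slen,
    )


def generate_hit_tables(
    truth: TruthSet,
    panel: SpeciesPanel,
    config: GeneratorConfig,
) -> SyntheticInputs:
    """Generate the proteome and every hit/call table, consistent with the truth.

    Genes of planted age X receive detectable hits only to panel species at
    strata <= X (always including at least one species exactly at X, and the
    fly exactly when the truth says so); deeper species receive only
    sub-threshold decoy hits.  Planted families receive reciprocal self-hits
    satisfying every paralog-edge criterion, with near-miss decoy pairs that
    each violate exactly one criterion.  Planted-immune genes receive HMM hits
    that survive the multi-search e-value correction; decoy HMM hits do not.
    """
    rng_seq, rng_hits, rng_hmm, rng_decoy = _streams(config.seed, 6)[2:6]
    g = truth.genes
    dmel = "Drosophila_melanogaster"
    if dmel not in panel.strata:
        raise ValueError("panel must include Drosophila_melanogaster")

    by_stratum: dict[Stratum, list[str]] = {s: [] for s in Stratum}
    for sp in panel.species:
        if sp != panel.focal_species:
            by_stratum[panel.strata[sp]].append(sp)

    # --- proteome, isoforms, signal calls -------------------------------
    proteins: list[ProteinRecord] = []
    signal_calls: list[SignalPeptideCall] = []
    first_isoform: dict[str, str] = {}
    for gene, row in g.iterrows():
        length = int(row["length_aa"])
        seq = _make_sequence(rng_seq, length, int(row["net_charge"]))
        pid = f"{gene}.t1"
        first_isoform[gene] = pid
        proteins.append(ProteinRecord(pid, gene, seq))
        signal_calls.append(SignalPeptideCall(pid, bool(row["has_signal"])))
        if int(row["n_isoforms"]) > 1:
            short = max(30, int(length * rng_seq.uniform(0.5, 0.9)))
            pid2 = f"{gene}.t2"
            proteins.append(ProteinRecord(pid2, gene, seq[:short]))
            signal_calls.append(
                SignalPeptideCall(
                    pid2, bool(row["has_signal"]) and rng_seq.random() < 0.5
                )
            )

    # --- cross-species hit tables ---------------------------------------
    species_hits: dict[str, list[BlastHit]] = {
        sp: [] for sp in panel.species if sp != panel.focal_species
    }
    subject_counter = 0
    order = list(Stratum)
    for gene, row in g.iterrows():
        age = Stratum.from_name(row["age"])
        qlen = int(row["length_aa"])
        pid = first_isoform[gene]
        eligible = [sp for s in order if s <= age for sp in by_stratum[s]]
        eligible = [sp for sp in eligible if sp != dmel]
        chosen: list[str] = []
        if age > Stratum.WASP:
            at_age = [sp for sp in by_stratum[age] if sp != dmel]
            if at_age:
                chosen.append(str(rng_hits.choice(at_age)))
            others = [sp for sp in eligible if sp not in chosen]
            n_more = int(
                rng_hits.integers(0, max(1, config.max_supporting_species - len(chosen)) + 1)
            )
            if others and n_more:
                chosen += [
                    str(s)
                    for s in rng_hits.choice(others, size=min(n_more, len(others)), replace=False)
                ]
        if bool(row["has_dmel_hit"]):
            chosen.append(dmel)
        for sp in chosen:
            subject_counter += 1
            subject = f"{sp}_p{subject_counter:06d}"
            evalue = 10.0 ** -rng_hits.uniform(5, 35)
            species_hits[sp].append(
                _detectable_hit(rng_hits, pid, subject, sp, qlen, evalue)
            )
            if int(row["n_isoforms"]) > 1 and rng_hits.random() < 0.5:
                # duplicate isoform hit with a worse e-value: exercised by collapse
                species_hits[sp].append(
                    _detectable_hit(
                        rng_hits, f"{gene}.t2", subject, sp, qlen, min(1e-3, evalue * 10)
                    )
                )
        if config.decoys and age < Stratum.METAZOAN and rng_hits.random() < 0.3:
            deeper = [sp for s in order if s > age for sp in by_stratum[s] if sp != dmel]
            if deeper:
                sp = str(rng_hits.choice(deeper))
                subject_counter += 1
                species_hits[sp].append(
                    _decoy_hit(rng_hits, pid, f"{sp}_p{subject_counter:06d}", sp, qlen)
                )

    # --- fly table additions and reciprocal-best structure ---------------
    dmel_to_nv: list[BlastHit] = []
    dmel_immune_table: dict[str, str] = {}
    rbh_genes = g.index[g["immune_source"] == "rbh_dmel"]
    for i, gene in enumerate(rbh_genes, start=1):
        partner = f"FBgn{i:05d}"
        qlen = int(g.loc[gene, "length_aa"])
        # mutual best: clearly the best fly hit of either side, yet less
        # significant than within-family self-hits (paralogy beats fly orthology)
        species_hits[dmel].append(
            _detectable_hit(rng_hits, first_isoform[gene], partner, dmel, qlen, 1e-38)
        )
        dmel_to_nv.append(
            _detectable_hit(rng_hits, partner, first_isoform[gene], panel.focal_species, qlen, 1e-38)
        )
        dmel_immune_table[partner] = str(g.loc[gene, "immune_class"])
    # a few fly orthologs without a published immune annotation
    nonimmune_dmel = g.index[(g["immune_source"] == "") & g["has_dmel_hit"]]
    for i, gene in enumerate(nonimmune_dmel[: max(2, len(nonimmune_dmel) // 20)], start=1):
        partner = f"FBgn9{i:04d}"
        qlen = int(g.loc[gene, "length_aa"])
        species_hits[dmel].append(
            _detectable_hit(rng_hits, first_isoform[gene], partner, dmel, qlen, 1e-37)
        )
        dmel_to_nv.append(
            _detectable_hit(rng_hits, partner, first_isoform[gene], panel.focal_species, qlen, 1e-37)
        )

    # --- self-hits: planted families as cliques --------------------------
    self_hits: list[BlastHit] = []
    lengths = g["length_aa"].to_dict()
    for _, members in g.groupby("family_id"):
        ids = sorted(members.index)
        if len(ids) < 2:
            continue
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                la, lb = int(lengths[a]), int(lengths[b])
                longer = max(la, lb)
                align = int(math.ceil(rng_hits.uniform(0.6, 0.95) * longer))
                self_hits.append(
                    BlastHit(
                        query_protein=first_isoform[a],
                        subject_protein=first_isoform[b],
                        subject_species=panel.focal_species,
                        evalue=10.0 ** -rng_hits.uniform(40, 60),
                        bitscore=round(float(rng_hits.uniform(120, 600)), 1),
                        pct_positives=round(float(rng_hits.uniform(40, 90)), 2),
                        align_len=align,
                        query_len=la,
                        subject_len=lb,
                    )
                )

    if config.decoys:
        self_hits += _near_miss_pairs(g, first_isoform, rng_decoy)

    # --- HMM hits ---------------------------------------------------------
    models_by_class: dict[str, list[str]] = {}
    for model, cls in HMM_MODEL_CLASSES.items():
        models_by_class.setdefault(cls, []).append(model)
    hmm_hits_raw: list[tuple[str, str, float]] = []
    hmm_genes = g.index[g["immune_source"] == "hmm"]
    for gene in hmm_genes:
        cls = str(g.loc[gene, "immune_class"])
        model = str(rng_hmm.choice(models_by_class[cls]))
        raw = float(rng_hmm.uniform(1e-30, 0.9 / 25))  # corrected stays <= 0.9
        hmm_hits_raw.append((first_isoform[gene], model, raw))
        if rng_hmm.random() < 0.15:  # a weaker second-model hit, still retained
            other = str(rng_hmm.choice(sorted(HMM_MODEL_CLASSES)))
            hmm_hits_raw.append(
                (first_isoform[gene], other, float(rng_hmm.uniform(0.91 / 25, 1.0 / 25)))
            )
    if config.decoys:
        nonimmune_pool = g.index[g["immune_source"] == ""].to_numpy()
        n_decoy = min(max(2, len(g) // 200), nonimmune_pool.size)
        decoy_genes = rng_hmm.choice(nonimmune_pool, size=n_decoy, replace=False)
        for gene in decoy_genes:
            model = str(rng_hmm.choice(sorted(HMM_MODEL_CLASSES)))
            hmm_hits_raw.append(
                (first_isoform[gene], model, float(rng_hmm.uniform(1.01 / 25, 5.0)))
            )

    amp_genes = sorted(g.index[g["immune_source"] == "amp_list"])
    return SyntheticInputs(
        proteins=proteins,
        signal_calls=signal_calls,
        species_hits=species_hits,
        self_hits=self_hits,
        dmel_to_nv_hits=dmel_to_nv,
        hmm_hits_raw=hmm_hits_raw,
        amp_genes=amp_genes,
        dmel_immune_table=dmel_immune_table,
    )


def _near_miss_pairs(
    g: pd.DataFrame,
    first_isoform: dict[str, str],
    rng: np.random.Generator,
) -> list[BlastHit]:
    """Reciprocal hit pairs between singleton genes, each failing one edge criterion."""
    fam_sizes = g.groupby("family_id")["length_aa"].size()
    singleton_fams = set(fam_sizes.index[fam_sizes == 1])
    singles = sorted(g.index[g["family_id"].isin(singleton_fams)])
    if len(singles) < 8:
        return []
    n_pairs = min(max(2, len(g) // 500), len(singles) // 2)
    picked = rng.choice(np.array(singles), size=2 * n_pairs, replace=False)
    hits: list[BlastHit] = []
    lengths = g["length_aa"].to_dict()
    for j in range(n_pairs):
        a, b = str(picked[2 * j]), str(picked[2 * j + 1])
        la, lb = int(lengths[a]), int(lengths[b])
        longer = max(la, lb)
        failure = j % 3
        evalue, positives = 10.0 ** -rng.uniform(10, 20), round(float(rng.uniform(40, 90)), 2)
        align = int(math.ceil(0.75 * longer))
        if failure == 0:  # e-value just past the paralog bound
            evalue = float(rng.uniform(2e-4, 1e-3))
        elif failure == 1:  # positives below 30
            positives = round(float(rng.uniform(10, 29)), 2)
        else:  # covers under half of the longer protein
            align = max(1, int(math.floor(rng.uniform(0.1, 0.45) * longer)))
        for qa, sb, ql, sl in ((a, b, la, lb), (b, a, lb, la)):
            hits.append(
                BlastHit(
                    query_protein=first_isoform[qa],
                    subject_protein=first_isoform[sb],
                    subject_species="self",
                    evalue=evalue,
                    bitscore=round(float(rng.uniform(50, 200)), 1),
                    pct_positives=positives,
                    align_len=align,
                    query_len=ql,
                    subject_len=sl,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Convenience wrappers
# ---------------------------------------------------------------------------


def generate_all(
    config: GeneratorConfig,
    panel: SpeciesPanel | None = None,
) -> tuple[TruthSet, list[CountRecord], SyntheticInputs, SpeciesPanel]:
    panel = panel or default_panel()
    truth = generate_truth(config)
    counts = generate_counts(truth, config)
    inputs = generate_hit_tables(truth, panel, config)
    return truth, counts, inputs, panel


def write_inputs(
    outdir: str | Path,
    truth: TruthSet,
    counts: Sequence[CountRecord],
    inputs: SyntheticInputs,
    panel: SpeciesPanel,
) -> dict[str, Path]:
    """Write every generated table under ``outdir`` and return the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hits_dir = outdir / "species_hits"
    hits_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["truth"] = outdir / "truth.tsv"
    truth.to_tsv(paths["truth"])
    paths["counts"] = outdir / "counts.tsv"
    write_counts(counts, paths["counts"])
    paths["proteins_fasta"] = outdir / "proteins.fasta"
    paths["isoform_map"] = outdir / "isoform_map.tsv"
    write_proteins(inputs.proteins, paths["proteins_fasta"], paths["isoform_map"])
    paths["signal_calls"] = outdir / "signal_calls.tsv"
    write_signal_calls(inputs.signal_calls, paths["signal_calls"])
    paths["panel"] = outdir / "species_panel.tsv"
    write_species_panel(panel, paths["panel"])
    paths["species_hits_dir"] = hits_dir
    for sp, hits in sorted(inputs.species_hits.items()):
        write_blast_table(hits, hits_dir / f"{sp}.tsv")
    paths["self_hits"] = outdir / "self_hits.tsv"
    write_blast_table(inputs.self_hits, paths["self_hits"])
    paths["dmel_to_nv"] = outdir / "dmel_to_nv.tsv"
    write_blast_table(inputs.dmel_to_nv_hits, paths["dmel_to_nv"])
    paths["hmm_hits"] = outdir / "hmm_hits.tsv"
    with paths["hmm_hits"].open("w") as fh:
        fh.write("protein_id\tmodel_name\tevalue\n")
        for pid, model, ev in inputs.hmm_hits_raw:
            fh.write(f"{pid}\t{model}\t{ev!r}\n")
    paths["amp_list"] = outdir / "amp_list.tsv"
    write_gene_list(inputs.amp_genes, paths["amp_list"])
    paths["dmel_immune"] = outdir / "dmel_immune.tsv"
    with paths["dmel_immune"].open("w") as fh:
        fh.write("dmel_gene\timmune_class\n")
        for gene in sorted(inputs.dmel_immune_table):
            fh.write(f"{gene}\t{inputs.dmel_immune_table[gene]}\n")
    paths["model_classes"] = outdir / "hmm_model_classes.tsv"
    with paths["model_classes"].open("w") as fh:
        fh.write("model_name\timmune_class\n")
        for model in sorted(inputs.model_class_map):
            fh.write(f"{model}\t{inputs.model_class_map[model]}\n")
    return paths
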