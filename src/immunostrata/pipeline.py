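"""End-to-end orchestration: read inputs, run every stage, merge per-gene annotations.

Every numeric threshold the stages use is surfaced as a named config field
with its standard value as default, and the summary records every
filtered-row count so the accounting (unexpressed / low-expression-filtered /
analyzable genes, per-source catalog totals, stage counts) is reproducible on
any input.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import catalog as catalog_mod
from . import enrichment as enrich_mod
from .de import (
    DEConfig,
    STATUS_NO_EXPRESSION,
    STATUS_FILTERED,
    STATUS_UP,
    STATUS_DOWN,
    run_de,
)
from .families import ParalogCriteria, build_families, multi_copy_flags, paralog_edges
from .io_tables import (
    aggregate_signal_calls,
    gene_lengths,
    protein_to_gene_map,
    read_blast_table,
    read_counts,
    read_gene_list,
    read_proteins,
    read_signal_calls,
    read_species_panel,
    to_gene_level,
    _read_tsv_rows,
)
from .screen import net_charge, novelty_summary, screen
from .strata import assign_all_strata, expression_class, stratum_table

log = logging.getLogger("immunostrata")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


class PipelineConfig(BaseModel):
    """Paths to every input plus all analysis thresholds."""

    counts: Path
    proteins_fasta: Path
    isoform_map: Path
    signal_calls: Path
    species_panel: Path
    species_hits_dir: Path
    self_hits: Path
    dmel_to_nv: Path
    hmm_hits: Path
    amp_list: Path
    dmel_immune: Path
    model_classes: Path
    outdir: Path = Path("immunostrata_out")

    fdr_level: float = Field(0.10, gt=0, lt=1)
    hmm_n_searches: int = Field(25, ge=1)
    blast_evalue_cutoff: float = Field(0.001, gt=0)
    paralog_evalue_cutoff: float = Field(1e-4, gt=0)
    detect_min_coverage: float = Field(0.5, ge=0, le=1)
    detect_min_positives: float = Field(30.0, ge=0, le=100)
    paralog_min_coverage: float = Field(0.5, ge=0, le=1)
    max_candidate_len: int = Field(300, gt=0)
    iqr_low: int = 134
    iqr_high: int = 456
    sigma_prior: float = Field(0.5, gt=0)
    dmel_species: str = "Drosophila_melanogaster"


class PipelineResult:
    def __init__(self, annotations: pd.DataFrame, summary: dict, tables: dict):
        self.annotations = annotations
        self.summary = summary
        self.tables = tables


def load_config(path: str | Path) -> PipelineConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _read_model_classes(path: Path) -> dict[str, str]:
    return {model: cls for model, cls in _read_tsv_rows(path, 2, header="model_name")}


def _read_hmm_hits(path: Path) -> list[tuple[str, str, float]]:
    rows = _read_tsv_rows(path, 3, header="protein_id")
    return [(pid, model, float(ev)) for pid, model, ev in rows]


def _read_dmel_immune(path: Path) -> dict[str, str]:
    return {gene: cls for gene, cls in _read_tsv_rows(path, 2, header="dmel_gene")}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in dependency order and write the merged outputs.

    Stage failures abort with the stage name; outputs written so far are left
    in place alongside a manifest of what completed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def _stage(name: str):
        log.info("stage: %s", name)
        manifest.append(name)
        (outdir / "manifest.txt").write_text("\n".join(manifest) + "\n")

    try:
        _stage("read_inputs")
        counts = read_counts(config.counts)
        proteins = read_proteins(config.proteins_fasta, config.isoform_map)
        pmap = protein_to_gene_map(proteins)
        lengths = gene_lengths(proteins)
        gene_universe = sorted(set(pmap.values()))
        signal_flags = aggregate_signal_calls(read_signal_calls(config.signal_calls), proteins)
        panel = read_species_panel(config.species_panel)

        _stage("de")
        de_cfg = DEConfig(fdr_level=config.fdr_level, sigma_prior=config.sigma_prior)
        de_results = run_de(counts, de_cfg)
        de_results.to_csv(outdir / "de_results.tsv", sep="\t", float_format="%.6g")

        _stage("strata")
        gene_hits: list = []
        for table in sorted(Path(config.species_hits_dir).glob("*.tsv")):
            species = table.stem
            hits = read_blast_table(table, subject_species=species)
            gene_hits.extend(to_gene_level(hits, pmap))
        assignments = assign_all_strata(
            gene_hits,
            panel,
            gene_universe,
            min_coverage=config.detect_min_coverage,
            min_pct_positives=config.detect_min_positives,
        )
        with (outdir / "strata.tsv").open("w") as fh:
            fh.write("gene_id\tstratum\tn_supporting_species\n")
            for g in gene_universe:
                a = assignments[g]
                fh.write(f"{g}\t{a.stratum.label()}\t{len(a.supporting_species)}\n")

        _stage("paralogs")
        self_hits = to_gene_level(
            read_blast_table(config.self_hits, subject_species="self"), pmap, pmap
        )
        best_nonhym: dict[str, float] = {}
        nonhym = panel.non_hymenopteran_species()
        for hit in gene_hits:
            if hit.subject_species in nonhym:
                g = hit.query_protein
                if g not in best_nonhym or hit.evalue < best_nonhym[g]:
                    best_nonhym[g] = hit.evalue
        criteria = ParalogCriteria(
            max_evalue=config.paralog_evalue_cutoff,
            min_coverage_of_longer=config.paralog_min_coverage,
        )
        edges = paralog_edges(self_hits, best_nonhym, criteria)
        families = build_families(edges, gene_universe)
        fam_of = {g: f for f in families for g in f.members}
        with (outdir / "families.tsv").open("w") as fh:
            fh.write("gene_id\tfamily_id\tfamily_size\n")
            for g in gene_universe:
                f = fam_of[g]
                fh.write(f"{g}\t{f.family_id}\t{f.size}\n")

        _stage("catalog")
        nv_to_dm = [
            h for h in gene_hits if h.subject_species == config.dmel_species
        ]
        dm_hits_raw = read_blast_table(config.dmel_to_nv, subject_species=panel.focal_species)
        dm_identity = {h.query_protein: h.query_protein for h in dm_hits_raw}
        dm_to_nv = to_gene_level(dm_hits_raw, dm_identity, pmap)
        # RBH needs subject ids at gene level on the forward table too
        nv_to_dm_genes = [h for h in nv_to_dm]
        rbh_pairs = catalog_mod.reciprocal_best_hits(nv_to_dm_genes, dm_to_nv)
        dmel_immune = _read_dmel_immune(config.dmel_immune)
        rbh_annotations = catalog_mod.transfer_dmel_annotation(rbh_pairs, dmel_immune)
        hmm_hits = catalog_mod.correct_and_filter_hmm(
            _read_hmm_hits(config.hmm_hits), n_searches=config.hmm_n_searches
        )
        model_classes = _read_model_classes(config.model_classes)
        hmm_annotations = catalog_mod.hmm_annotations_from_hits(hmm_hits, pmap, model_classes)
        amp_genes = read_gene_list(config.amp_list)
        immune, catalog_summary = catalog_mod.merge_catalog(
            amp_genes, rbh_annotations, hmm_annotations, gene_universe
        )
        with (outdir / "immune_catalog.tsv").open("w") as fh:
            fh.write("gene_id\tsource\timmune_class\tdetail\n")
            for g in sorted(immune):
                a = immune[g]
                fh.write(f"{g}\t{a.source}\t{a.immune_class}\t{a.detail}\n")

        _stage("screen")
        dmel_hit_genes = {h.query_protein for h in nv_to_dm}
        candidates, stage_counts = screen(
            de_results,
            set(immune),
            proteins,
            signal_flags,
            dmel_hit_genes,
            max_len=config.max_candidate_len,
        )
        with (outdir / "candidates.tsv").open("w") as fh:
            fh.write("gene_id\tlength_aa\thas_signal\thas_dmel_hit\tnet_charge\tstage_reached\n")
            for c in candidates:
                fh.write(
                    f"{c.gene_id}\t{c.length_aa}\t{c.has_signal}\t{c.has_dmel_hit}\t"
                    f"{c.net_charge}\t{c.stage_reached}\n"
                )
        try:
            novelty = novelty_summary(
                de_results, set(immune), families, proteins, signal_flags,
                max_len=config.max_candidate_len,
            )
        except ValueError:
            novelty = {"numerator": 0, "denominator": 0, "fraction": float("nan")}

        _stage("stats")
        counts_tab, props_tab = stratum_table(assignments, de_results)
        battery = enrich_mod.class_enrichment(
            de_results, immune, assignments, families, proteins, signal_flags,
            max_len=config.max_candidate_len,
        )
        battery.to_csv(outdir / "enrichment.tsv", sep="\t", float_format="%.6g")
        iqr = enrich_mod.iqr_restricted_comparison(
            assignments, de_results, proteins, low=config.iqr_low, high=config.iqr_high
        )
        logistic = {}
        for youth in ("not_metazoan", "wasp_specific"):
            try:
                logistic[youth] = enrich_mod.logistic_youth_model(
                    assignments, de_results, proteins, youth_definition=youth
                )
            except ValueError as exc:
                log.warning("logistic model (%s) not fitted: %s", youth, exc)

        _stage("merge")
        multi = multi_copy_flags(families)
        charges = {}
        longest: dict[str, tuple[int, str]] = {}
        for p in proteins:
            if p.gene_id not in longest or p.length_aa > longest[p.gene_id][0]:
                longest[p.gene_id] = (p.length_aa, p.sequence)
        for g, (_, seq) in longest.items():
            charges[g] = net_charge(seq)
        cand_stage = {c.gene_id: c.stage_reached for c in candidates}
        rows = []
        for g in gene_universe:
            de_row = de_results.loc[g] if g in de_results.index else None
            ann = immune.get(g)
            fam = fam_of[g]
            rows.append(
                {
                    "gene_id": g,
                    "base_mean": de_row["base_mean"] if de_row is not None else np.nan,
                    "log2fc": de_row["log2fc"] if de_row is not None else np.nan,
                    "pvalue": de_row["pvalue"] if de_row is not None else np.nan,
                    "padj": de_row["padj"] if de_row is not None else np.nan,
                    "status": de_row["status"] if de_row is not None else "",
                    "immune_source": ann.source if ann else "",
                    "immune_class": ann.immune_class if ann else "",
                    "stratum": assignments[g].stratum.label(),
                    "family_id": fam.family_id,
                    "family_size": fam.size,
                    "multi_copy": multi[g],
                    "length_aa": lengths.get(g, np.nan),
                    "has_signal": bool(signal_flags.get(g, False)),
                    "net_charge": charges.get(g, np.nan),
                    "candidate_stage": cand_stage.get(g, ""),
                }
            )
        annotations = pd.DataFrame(rows).set_index("gene_id")
        annotations.to_csv(outdir / "gene_annotations.tsv", sep="\t", float_format="%.6g")

        status = de_results["status"]
        n_analyzable = int((~status.isin([STATUS_NO_EXPRESSION, STATUS_FILTERED])).sum())
        n_up = int((status == STATUS_UP).sum())
        n_down = int((status == STATUS_DOWN).sum())
        expressed_cls = de_results["status"].map(expression_class)
        summary = {
            "n_genes": len(gene_universe),
            "de": {
                "n_up": n_up,
                "n_down": n_down,
                "n_no_expression": int((status == STATUS_NO_EXPRESSION).sum()),
                "n_low_expression_filtered": int((status == STATUS_FILTERED).sum()),
                "n_analyzable": n_analyzable,
                "pct_up_of_analyzable": 100.0 * n_up / max(1, n_analyzable),
                "pct_down_of_analyzable": 100.0 * n_down / max(1, n_analyzable),
                "filter_threshold": de_results.attrs.get("filter_threshold"),
                "filter_cap_median_base_mean": de_results.attrs.get("filter_cap"),
                "size_factors": list(de_results.attrs.get("size_factors", ())),
            },
            "catalog": catalog_summary,
            "n_rbh_pairs": len(rbh_pairs),
            "strata_counts": counts_tab.to_dict(),
            "strata_proportions_pct": (100 * props_tab).round(2).to_dict(),
            "screen_stage_counts": stage_counts,
            "novelty": novelty,
            "enrichment": {
                name: {
                    "odds_ratio": float(row["odds_ratio"]),
                    "pvalue": float(row["pvalue"]),
                    "pct_class_induced": 100.0 * float(row["prop_class"]),
                    "pct_rest_induced": 100.0 * float(row["prop_rest"]),
                }
                for name, row in battery.iterrows()
            },
            "iqr_restricted": {
                "configured_bounds": list(iqr["configured_bounds"]),
                "computed_induced_iqr": list(iqr["computed_induced_iqr"]),
                "n_genes": iqr["n_genes"],
                "proportions_pct": (100 * iqr["proportions"]).round(2).to_dict(),
            },
            "logistic": {
                youth: {
                    "coefficients": fit.coefficients,
                    "std_errors": fit.std_errors,
                    "pvalues": fit.pvalues,
                    "n_obs": fit.n_obs,
                }
                for youth, fit in logistic.items()
            },
            "n_expression_classes": expressed_cls.value_counts(dropna=True).to_dict(),
        }
        with (outdir / "summary.json").open("w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)

        tables = {
            "de_results": de_results,
            "strata_counts": counts_tab,
            "strata_proportions": props_tab,
            "enrichment": battery,
            "iqr": iqr,
            "logistic": logistic,
            "families": families,
            "immune": immune,
            "candidates": candidates,
            "assignments": assignments,
        }
        return PipelineResult(annotations, summary, tables)
    except Exception as exc:
        stage = manifest[-1] if manifest else "init"
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
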