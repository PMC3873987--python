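"""The generator: determinism, planted rates, and consistency of emitted tables
with the planted truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunostrata.families import build_families, paralog_edges
from immunostrata.io_tables import Stratum, to_gene_level
from immunostrata.screen import net_charge
from immunostrata.strata import assign_all_strata, is_detectable_homolog
from immunostrata.synth import (
    GeneratorConfig,
    default_panel,
    generate_counts,
    generate_hit_tables,
    generate_truth,
)


def small_cfg(**kw):
    base = dict(seed=42, n_genes=600)
    base.update(kw)
    return GeneratorConfig(**base)


def test_planted_enrichment_directions_hold_across_seeds():
    """The generator links induction to immunity and youth: the planted
    immune odds ratio exceeds 1 and young genes are over-represented among
    induced genes in nearly every seed."""
    from immunostrata.enrichment import ContingencyTable2x2, fisher_exact_2x2

    immune_ok = youth_ok = 0
    n_seeds = 10
    for seed in range(n_seeds):
        t = generate_truth(GeneratorConfig(seed=1000 + seed, n_genes=4000)).genes
        induced = t["induced"].to_numpy()
        immune = (t["immune_source"] != "").to_numpy()
        young = t["age"].isin(["Wasp", "Hymenoptera"]).to_numpy()
        odds, _ = fisher_exact_2x2(
            ContingencyTable2x2(
                int((immune & induced).sum()),
                int((immune & ~induced).sum()),
                int((~immune & induced).sum()),
                int((~immune & ~induced).sum()),
            )
        )
        immune_ok += odds > 1
        youth_ok += induced[young].mean() > induced[~young].mean()
    assert immune_ok >= 9 and youth_ok >= 9


class TestTruth:
    def test_same_seed_is_identical(self):
        a = generate_truth(small_cfg()).genes
        b = generate_truth(small_cfg()).genes
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_truth(small_cfg()).genes
        b = generate_truth(small_cfg(seed=43)).genes
        assert not a.equals(b)

    def test_zero_induced_fraction(self):
        t = generate_truth(small_cfg(fraction_induced=0.0)).genes
        assert (t["lfc"] <= 0).all()

    def test_planted_induced_count_within_binomial_interval(self):
        cfg = GeneratorConfig(seed=7, n_genes=20000, fraction_induced=0.013)
        t = generate_truth(cfg).genes
        n, p = 20000, 0.013
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= t["induced"].sum() <= hi

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(seed=1, fraction_induced=0.9, fraction_repressed=0.2)
        with pytest.raises(ValueError):
            GeneratorConfig(seed=1, fraction_zero_expression=-0.1)


class TestCounts:
    def test_zero_expression_genes_emit_double_zero(self):
        cfg = small_cfg(fraction_zero_expression=0.3)
        truth = generate_truth(cfg)
        counts = {c.gene_id: c for c in generate_counts(truth, cfg)}
        for gene, row in truth.genes[truth.genes["zero_expression"]].iterrows():
            assert (counts[gene].count_infected, counts[gene].count_uninfected) == (0, 0)

    def test_poisson_limit_at_zero_dispersion(self):
        cfg = GeneratorConfig(
            seed=3, n_genes=4000, dispersion=0.0,
            fraction_induced=0.0, fraction_repressed=0.0, fraction_zero_expression=0.0,
            baseline_meanlog=np.log(50.0), baseline_sdlog=0.0,
            size_factor_infected=1.0, size_factor_uninfected=1.0,
        )
        counts = generate_counts(generate_truth(cfg), cfg)
        k = np.array([c.count_infected for c in counts], float)
        assert np.var(k) / np.mean(k) == pytest.approx(1.0, rel=0.1)

    def test_null_genes_have_zero_mean_log_ratio(self):
        cfg = GeneratorConfig(
            seed=4, n_genes=5000, fraction_induced=0.0, fraction_repressed=0.0,
            fraction_zero_expression=0.0, baseline_meanlog=np.log(200.0),
            baseline_sdlog=0.3, size_factor_infected=1.0, size_factor_uninfected=1.0,
        )
        counts = generate_counts(generate_truth(cfg), cfg)
        ratios = [
            np.log2((c.count_infected + 0.5) / (c.count_uninfected + 0.5)) for c in counts
        ]
        assert abs(np.mean(ratios)) < 0.02


@pytest.fixture(scope="module")
def generated():
    cfg = small_cfg(seed=11, n_genes=500)
    truth = generate_truth(cfg)
    panel = default_panel()
    inputs = generate_hit_tables(truth, panel, cfg)
    return cfg, truth, panel, inputs


class TestHitTables:

    def test_wasp_genes_have_no_detectable_cross_species_hits(self, generated):
        _, truth, panel, inputs = generated
        wasp_genes = set(truth.genes.index[truth.genes["age"] == "Wasp"])
        for hits in inputs.species_hits.values():
            for h in hits:
                gene = h.query_protein.rsplit(".", 1)[0]
                if gene in wasp_genes:
                    assert not is_detectable_homolog(h)

    def test_metazoan_genes_have_an_outgroup_hit_above_thresholds(self, generated):
        _, truth, panel, inputs = generated
        outgroups = {sp for sp, s in panel.strata.items() if s == Stratum.METAZOAN}
        seen = set()
        for sp in outgroups:
            for h in inputs.species_hits.get(sp, []):
                if is_detectable_homolog(h):
                    seen.add(h.query_protein.rsplit(".", 1)[0])
        metazoan = set(truth.genes.index[truth.genes["age"] == "Metazoan"])
        assert metazoan <= seen

    def test_strata_recovered_exactly(self, generated):
        _, truth, panel, inputs = generated
        pmap = {p.protein_id: p.gene_id for p in inputs.proteins}
        gene_hits = []
        for sp, hits in inputs.species_hits.items():
            gene_hits.extend(to_gene_level(hits, pmap))
        out = assign_all_strata(gene_hits, panel, list(truth.genes.index))
        recovered = {g: a.stratum.label() for g, a in out.items()}
        assert recovered == truth.genes["age"].to_dict()

    def test_planted_families_recovered_exactly(self, generated):
        _, truth, panel, inputs = generated
        pmap = {p.protein_id: p.gene_id for p in inputs.proteins}
        self_hits = to_gene_level(inputs.self_hits, pmap, pmap)
        nonhym = panel.non_hymenopteran_species()
        best = {}
        for sp, hits in inputs.species_hits.items():
            if sp not in nonhym:
                continue
            for h in hits:
                g = pmap[h.query_protein]
                best[g] = min(best.get(g, np.inf), h.evalue)
        fams = build_families(
            paralog_edges(self_hits, best), list(truth.genes.index)
        )
        got = sorted(sorted(f.members) for f in fams)
        planted = sorted(sorted(m) for m in truth.family_partition())
        assert got == planted

    def test_sequences_realize_planted_lengths_and_charges(self, generated):
        _, truth, _, inputs = generated
        longest = {}
        for p in inputs.proteins:
            if p.gene_id not in longest or p.length_aa > longest[p.gene_id].length_aa:
                longest[p.gene_id] = p
        for gene, row in truth.genes.iterrows():
            p = longest[gene]
            assert p.length_aa == row["length_aa"]
            assert net_charge(p.sequence) == row["net_charge"]

    def test_hmm_hits_pass_filter_only_for_planted_immune_genes(self, generated):
        from immunostrata.catalog import correct_and_filter_hmm

        _, truth, _, inputs = generated
        kept = correct_and_filter_hmm(inputs.hmm_hits_raw, n_searches=25)
        kept_genes = {h.protein_id.rsplit(".", 1)[0] for h in kept}
        hmm_planted = set(truth.genes.index[truth.genes["immune_source"] == "hmm"])
        assert kept_genes == hmm_planted

    def test_tables_byte_identical_across_runs(self, generated, tmp_path):
        from immunostrata.synth import generate_all, write_inputs

        cfg = small_cfg(seed=19, n_genes=150)
        for d in ("a", "b"):
            write_inputs(tmp_path / d, *generate_all(cfg))
        files_a = sorted((tmp_path / "a").rglob("*.tsv")) + sorted((tmp_path / "a").rglob("*.fasta"))
        assert files_a
        for fa in files_a:
            fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
            assert fa.read_bytes() == fb.read_bytes()
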