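"""Size factors, blind dispersion, the conditional exact NB test and filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from immunostrata.de import (
    DEConfig,
    estimate_blind_dispersion,
    estimate_size_factors,
    independent_filter_and_adjust,
    nb_test,
    run_de,
)
from immunostrata.io_tables import CountRecord
from immunostrata.synth import GeneratorConfig, generate_counts, generate_truth


def cr(rows):
    return [CountRecord(f"g{i}", a, b) for i, (a, b) in enumerate(rows)]


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        sf = estimate_size_factors(cr([(10, 10), (50, 50), (7, 7)]))
        assert sf.s_infected == pytest.approx(1.0)
        assert sf.s_uninfected == pytest.approx(1.0)

    def test_doubled_library(self):
        sf = estimate_size_factors(cr([(10, 20), (30, 60), (5, 10)]))
        assert sf.s_infected == pytest.approx(1 / np.sqrt(2))
        assert sf.s_uninfected == pytest.approx(np.sqrt(2))

    def test_matches_median_of_ratios_oracle_ignoring_zero_rows(self):
        rows = [(10, 10), (20, 40), (0, 5)]
        sf = estimate_size_factors(cr(rows))
        # oracle: enumerate ratios over the all-positive rows only
        ratios = []
        for a, b in rows[:2]:
            gm = np.sqrt(a * b)
            ratios.append((a / gm, b / gm))
        expect = np.median(np.array(ratios), axis=0)
        assert sf.s_infected == pytest.approx(expect[0])
        assert sf.s_uninfected == pytest.approx(expect[1])

    def test_no_all_positive_row_raises(self):
        with pytest.raises(ValueError):
            estimate_size_factors(cr([(0, 5), (7, 0)]))


class TestBlindDispersion:
    def _fit(self, counts, **kw):
        sf = estimate_size_factors(counts)
        return estimate_blind_dispersion(counts, sf, DEConfig(**kw))

    def test_moment_estimates(self, rng):
        from immunostrata.de import SizeFactors

        filler = cr([(int(a), int(b)) for a, b in rng.poisson(20, size=(200, 2))])
        counts = [CountRecord("eq", 15, 15), CountRecord("uneq", 10, 20)] + filler
        fit = estimate_blind_dispersion(
            counts, SizeFactors(1.0, 1.0), DEConfig(min_informative_genes=10)
        )
        mom = dict(zip(fit.gene_ids, fit.alpha_mom))
        assert mom["eq"] == 0.0  # zero two-point variance
        assert mom["uneq"] == pytest.approx(35 / 225)  # m=15, v=50

    def test_too_few_informative_genes_raises(self):
        with pytest.raises(ValueError, match="larger"):
            self._fit(cr([(5, 5)] * 20))

    def test_recovers_dispersion_scale_on_simulated_data(self):
        cfg = GeneratorConfig(
            seed=5,
            n_genes=5000,
            dispersion=0.2,
            fraction_induced=0.0,
            fraction_repressed=0.0,
            fraction_zero_expression=0.0,
            baseline_meanlog=np.log(100.0),
            baseline_sdlog=0.5,
        )
        counts = generate_counts(generate_truth(cfg), cfg)
        fit = self._fit(counts)
        assert 0.1 <= float(np.nanmedian(fit.alpha_map)) <= 0.4


class TestExactTest:
    def _results(self, counts, **kw):
        from immunostrata.de import SizeFactors

        cfg = DEConfig(min_informative_genes=10, **kw)
        sf = SizeFactors(1.0, 1.0)  # the examples assume equal library depths
        disp = estimate_blind_dispersion(counts, sf, cfg)
        return nb_test(counts, sf, disp, cfg)

    def test_symmetric_counts_give_null_result(self, rng):
        filler = cr([(int(a), int(b)) for a, b in rng.poisson(30, size=(300, 2))])
        counts = [CountRecord("sym", 25, 25)] + filler
        res = self._results(counts)
        assert res.loc["sym", "log2fc"] == pytest.approx(0.0)
        assert res.loc["sym", "pvalue"] == pytest.approx(1.0)

    def test_double_zero_is_no_expression_without_pvalue(self, rng):
        filler = cr([(int(a), int(b)) for a, b in rng.poisson(30, size=(300, 2))])
        counts = [CountRecord("zero", 0, 0)] + filler
        res = self._results(counts)
        assert res.loc["zero", "status"] == "no_expression"
        assert np.isnan(res.loc["zero", "pvalue"])

    def test_pvalue_matches_bruteforce_enumeration(self):
        """p for counts (30, 5), unit size factors, alpha=0.1 equals an
        exhaustive sum of NB split probabilities over the conditioned total."""
        from immunostrata.de import _exact_nb_pvalue

        k1, k2, alpha = 30, 5, 0.1
        mu = (k1 + k2) / 2
        # independent oracle: direct enumeration with scipy pmfs
        r = 1 / alpha
        p_nb = r / (r + mu)
        a = np.arange(k1 + k2 + 1)
        probs = stats.nbinom.pmf(a, r, p_nb) * stats.nbinom.pmf(k1 + k2 - a, r, p_nb)
        expected = probs[probs <= probs[k1] * (1 + 1e-8)].sum() / probs.sum()
        got = _exact_nb_pvalue(k1, k2, mu, mu, alpha)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_dispersion_raises(self):
        counts = cr([(30, 5)])
        sf = estimate_size_factors(counts)
        from immunostrata.de import DispersionFit

        empty = DispersionFit(["g0"], np.array([np.nan]), 0.1, 0.0, np.array([np.nan]), 0.5)
        with pytest.raises(ValueError, match="dispersion"):
            nb_test(counts, sf, empty)


class TestIndependentFilter:
    def _frame(self, base_mean, pvalue):
        n = len(base_mean)
        return pd.DataFrame(
            {
                "base_mean": base_mean,
                "log2fc": np.ones(n),
                "pvalue": pvalue,
                "status": [""] * n,
            },
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )

    def test_vacuous_filter_equals_plain_bh(self, rng):
        pv = rng.uniform(size=60)
        pv[:5] = 1e-5
        res = self._frame(np.full(60, 100.0), pv)
        out = independent_filter_and_adjust(res, fdr_level=0.10)
        _, padj, *_ = multipletests(pv, alpha=0.10, method="fdr_bh")
        assert np.allclose(out["padj"].to_numpy(), padj)

    def test_filtering_never_loses_rejections(self, rng):
        base = np.concatenate([np.full(10, 500.0), rng.uniform(1, 5, 90)])
        pv = np.concatenate([np.full(10, 0.001), rng.uniform(size=90)])
        res = self._frame(base, pv)
        out = independent_filter_and_adjust(res, fdr_level=0.10)
        plain_rej = multipletests(pv, alpha=0.10, method="fdr_bh")[0].sum()
        got_rej = out["status"].isin(["up", "down"]).sum()
        # grid-search oracle over the same candidate thresholds
        cap = np.median(base)
        cands = [-np.inf] + [q for q in np.quantile(base, np.arange(96) / 100) if q <= cap]
        oracle = max(
            multipletests(pv[base > t], alpha=0.10, method="fdr_bh")[0].sum()
            for t in cands
        )
        assert got_rej == oracle >= plain_rej

    def test_threshold_capped_at_median_base_mean(self, rng):
        base = rng.lognormal(3, 1, 200)
        pv = rng.uniform(size=200)
        out = independent_filter_and_adjust(self._frame(base, pv))
        thr = out.attrs["filter_threshold"]
        assert thr is None or thr <= np.median(base)

    def test_padj_monotone_in_p_within_filtered_set(self, rng):
        base = rng.lognormal(2, 1, 150)
        pv = rng.uniform(size=150)
        out = independent_filter_and_adjust(self._frame(base, pv))
        kept = out[out["padj"].notna()].sort_values("pvalue")
        assert (np.diff(kept["padj"].to_numpy()) >= -1e-12).all()


class TestRunDE:
    def test_label_symmetry_under_library_swap(self, rng):
        cfg = GeneratorConfig(seed=9, n_genes=1200, baseline_meanlog=np.log(40))
        counts = generate_counts(generate_truth(cfg), cfg)
        swapped = [
            CountRecord(c.gene_id, c.count_uninfected, c.count_infected) for c in counts
        ]
        a = run_de(counts)
        b = run_de(swapped)
        assert np.allclose(a["log2fc"].to_numpy(), -b["log2fc"].to_numpy())
        pa, pb = a["pvalue"].to_numpy(), b["pvalue"].to_numpy()
        ok = ~np.isnan(pa)
        assert np.allclose(pa[ok], pb[ok])
        assert ((a["status"] == "up") == (b["status"] == "down")).all()

    def test_type_one_error_controlled_on_null_data(self):
        """No planted fold changes: up/down calls at FDR 10% are (nearly) absent
        across seeds, consistent with the BH guarantee."""
        total_calls = 0
        for seed in range(20):
            cfg = GeneratorConfig(
                seed=seed,
                n_genes=800,
                fraction_induced=0.0,
                fraction_repressed=0.0,
                fraction_zero_expression=0.05,
            )
            counts = generate_counts(generate_truth(cfg), cfg)
            res = run_de(counts)
            total_calls += int(res["status"].isin(["up", "down"]).sum())
        assert total_calls <= 4
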