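"""RBH orthology, annotation transfer, HMM e-value correction, catalog merge."""

import pytest

from immunostrata.catalog import (
    ImmuneAnnotation,
    correct_and_filter_hmm,
    merge_catalog,
    reciprocal_best_hits,
    transfer_dmel_annotation,
)

from conftest import make_hit


def _bruteforce_rbh(fwd, rev):
    """All-pairs oracle: best per query by (evalue, -bitscore); a shared best
    (exact tie on both keys) disqualifies; pair kept iff mutual."""

    def best(hits):
        out = {}
        for h in hits:
            out.setdefault(h.query_protein, []).append(h)
        result = {}
        for q, hs in out.items():
            key = min((h.evalue, -h.bitscore) for h in hs)
            tops = {h.subject_protein for h in hs if (h.evalue, -h.bitscore) == key}
            result[q] = next(iter(tops)) if len(tops) == 1 else None
        return result

    f, r = best(fwd), best(rev)
    return sorted((a, b) for a, b in f.items() if b is not None and r.get(b) == a)


class TestReciprocalBestHits:
    def test_mutual_unique_best_is_paired(self):
        fwd = [make_hit(query="a", subject="b", evalue=1e-20)]
        rev = [make_hit(query="b", subject="a", evalue=1e-18)]
        assert reciprocal_best_hits(fwd, rev) == [("a", "b")]

    def test_asymmetry_excludes_pair(self):
        fwd = [make_hit(query="a", subject="b", evalue=1e-20)]
        rev = [
            make_hit(query="b", subject="c", evalue=1e-30),
            make_hit(query="b", subject="a", evalue=1e-18),
        ]
        assert reciprocal_best_hits(fwd, rev) == []

    def test_evalue_tie_resolved_by_bitscore(self):
        fwd = [
            make_hit(query="a", subject="b", evalue=1e-20, bitscore=200.0),
            make_hit(query="a", subject="c", evalue=1e-20, bitscore=150.0),
        ]
        rev = [make_hit(query="b", subject="a", evalue=1e-20)]
        assert reciprocal_best_hits(fwd, rev) == [("a", "b")]

    def test_exact_tie_disqualifies(self):
        fwd = [
            make_hit(query="a", subject="b", evalue=1e-20, bitscore=200.0),
            make_hit(query="a", subject="c", evalue=1e-20, bitscore=200.0),
        ]
        rev = [make_hit(query="b", subject="a", evalue=1e-20)]
        assert reciprocal_best_hits(fwd, rev) == []

    def test_matches_bruteforce_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            fwd, rev = [], []
            for i in range(5):
                for j in range(5):
                    if rng.random() < 0.6:
                        fwd.append(
                            make_hit(
                                query=f"a{i}",
                                subject=f"b{j}",
                                evalue=float(10.0 ** -rng.integers(2, 6)),
                                bitscore=float(rng.integers(50, 90)),
                            )
                        )
                    if rng.random() < 0.6:
                        rev.append(
                            make_hit(
                                query=f"b{j}",
                                subject=f"a{i}",
                                evalue=float(10.0 ** -rng.integers(2, 6)),
                                bitscore=float(rng.integers(50, 90)),
                            )
                        )
            assert reciprocal_best_hits(fwd, rev) == _bruteforce_rbh(fwd, rev)

    def test_symmetry(self, rng):
        fwd = [
            make_hit(query=f"a{i}", subject=f"b{int(rng.integers(3))}",
                     evalue=float(10.0 ** -rng.integers(2, 9)))
            for i in range(4)
        ]
        rev = [
            make_hit(query=f"b{j}", subject=f"a{int(rng.integers(4))}",
                     evalue=float(10.0 ** -rng.integers(2, 9)))
            for j in range(3)
        ]
        ab = reciprocal_best_hits(fwd, rev)
        ba = reciprocal_best_hits(rev, fwd)
        assert sorted((b, a) for a, b in ab) == ba


class TestAnnotationTransfer:
    def test_listed_partner_transfers_class(self):
        out = transfer_dmel_annotation([("nv1", "FB1")], {"FB1": "recognition"})
        assert out == [ImmuneAnnotation("nv1", "rbh_dmel", "recognition", detail="FB1")]

    def test_unlisted_partner_gives_nothing(self):
        assert transfer_dmel_annotation([("nv1", "FB9")], {"FB1": "recognition"}) == []

    def test_counts(self):
        pairs = [("nv1", "FB1"), ("nv2", "FB2"), ("nv3", "FB3")]
        table = {"FB1": "signaling", "FB3": "amp"}
        assert len(transfer_dmel_annotation(pairs, table)) == 2


class TestHmmCorrection:
    def test_boundary_inclusive(self):
        kept = correct_and_filter_hmm([("p1", "PGRP", 0.04)], n_searches=25)
        assert len(kept) == 1 and kept[0].evalue_corrected == pytest.approx(1.0)

    def test_just_past_boundary_discarded(self):
        assert correct_and_filter_hmm([("p1", "PGRP", 0.05)], n_searches=25) == []

    def test_multi_model_keeps_smallest(self):
        hits = [("p1", "M2", 0.02), ("p1", "M1", 0.008)]
        kept = correct_and_filter_hmm(hits, n_searches=25)
        assert [h.model_name for h in kept] == ["M1"]

    def test_order_invariant(self, rng):
        hits = [
            (f"p{int(rng.integers(4))}", f"M{int(rng.integers(5))}", float(rng.uniform(0, 0.1)))
            for _ in range(20)
        ]
        a = correct_and_filter_hmm(hits, 25)
        b = correct_and_filter_hmm(list(reversed(hits)), 25)
        assert a == b

    def test_retained_set_shrinks_as_n_searches_grows(self, rng):
        hits = [
            (f"p{i}", "M", float(rng.uniform(0, 0.2))) for i in range(30)
        ]
        prev = None
        for n in (1, 5, 25, 100):
            kept = {h.protein_id for h in correct_and_filter_hmm(hits, n)}
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_invalid_n_searches(self):
        with pytest.raises(ValueError):
            correct_and_filter_hmm([], n_searches=0)


class TestMergeCatalog:
    UNIVERSE = [f"g{i}" for i in range(20)]

    def test_precedence_counts_gene_once(self):
        final, summary = merge_catalog(
            ["g1"],
            [],
            [ImmuneAnnotation("g1", "hmm", "recognition")],
            self.UNIVERSE,
        )
        assert summary["total"] == 1
        assert final["g1"].source == "amp_list"
        assert final["g1"].immune_class == "amp"
        assert summary["raw_amp_list"] == 1 and summary["raw_hmm"] == 1

    def test_disjoint_sources_sum(self):
        final, summary = merge_catalog(
            ["g0", "g1", "g2"],
            [ImmuneAnnotation(f"g{i}", "rbh_dmel", "signaling") for i in (3, 4, 5, 6)],
            [ImmuneAnnotation(f"g{i}", "hmm", "recognition") for i in (7, 8, 9, 10, 11)],
            self.UNIVERSE,
        )
        assert summary["total"] == 12 == len(final)

    def test_empty_inputs_give_empty_catalog(self):
        final, summary = merge_catalog([], [], [], self.UNIVERSE)
        assert final == {} and summary["total"] == 0

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            merge_catalog(["mystery"], [], [], self.UNIVERSE)

    def test_total_never_exceeds_source_sum(self, rng):
        for _ in range(20):
            amp = [f"g{int(i)}" for i in rng.choice(20, size=3, replace=False)]
            rbh = [
                ImmuneAnnotation(f"g{int(i)}", "rbh_dmel", "signaling")
                for i in rng.choice(20, size=4, replace=False)
            ]
            hmm = [
                ImmuneAnnotation(f"g{int(i)}", "hmm", "recognition")
                for i in rng.choice(20, size=5, replace=False)
            ]
            final, summary = merge_catalog(amp, rbh, hmm, self.UNIVERSE)
            union = set(amp) | {a.gene_id for a in rbh} | {a.gene_id for a in hmm}
            assert summary["total"] == len(union) <= 12
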