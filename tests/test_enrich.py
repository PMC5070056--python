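"""Enrichment statistics: running-sum ES, one- and two-tailed analyses,
permutation p-values, BH adjustment, direction calls and consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mranet import (
    EnrichmentRecord,
    Regulon,
    RankedSignature,
    compute_signature,
    consensus,
    gsea_es,
    mra,
    regulons_from_truth,
    split_regulon,
    two_tailed_gsea,
    two_tailed_mra,
)
from mranet.enrich import INCONCLUSIVE, INDUCED, REPRESSED
from mranet.exceptions import InvalidInputError
from oracles import es_bruteforce


def _signature(logfc_by_gene):
    genes = list(logfc_by_gene)
    table = pd.DataFrame(
        {
            "logfc": [logfc_by_gene[g] for g in genes],
            "t": 0.0,
            "p": 1.0,
        },
        index=pd.Index(genes, name="gene"),
    )
    return RankedSignature(table)


def _regulon(tf, pos=(), neg=()):
    targets = {g: (1, 0.9) for g in pos}
    targets.update({g: (-1, -0.9) for g in neg})
    return Regulon(tf, targets)


class TestGseaES:
    def test_top_gene_hit_scores_one(self):
        genes = [f"g{i}" for i in range(10)]
        es = gsea_es(genes, np.linspace(5, 0.5, 10), {"g0"}, exponent=0.0)
        assert es == pytest.approx(1.0)

    def test_bottom_gene_hit_matches_enumeration(self):
        genes = [f"g{i}" for i in range(10)]
        w = np.linspace(5, 0.5, 10)
        es = gsea_es(genes, w, {"g9"}, exponent=0.0)
        assert es == pytest.approx(es_bruteforce(genes, w, {"g9"}, 0.0), abs=1e-12)
        assert es < 0  # trough just before the final hit

    def test_ten_gene_fixture_weighted(self):
        genes = ["a", "b", "c", "d", "e", "f", "g", "h", "i", "j"]
        weights = [3.1, 2.7, 2.0, 1.4, 1.1, 0.9, 0.6, 0.4, 0.2, 0.1]
        hits = {"b", "c", "h"}
        es = gsea_es(genes, weights, hits, exponent=1.0)
        assert es == pytest.approx(es_bruteforce(genes, weights, hits, 1.0), abs=1e-12)

    def test_random_lists_match_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 120))
            genes = [f"g{i}" for i in range(n)]
            weights = rng.normal(size=n)
            k = int(rng.integers(1, n // 2 + 1))
            hits = set(rng.choice(genes, size=k, replace=False).tolist())
            exp = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            es = gsea_es(genes, weights, hits, exp)
            assert es == pytest.approx(
                es_bruteforce(genes, weights, hits, exp), abs=1e-12
            )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_reversing_list_negates_score(self, seed):
        g = np.random.default_rng(seed)
        n = 40
        genes = [f"g{i}" for i in range(n)]
        weights = np.sort(g.normal(size=n))[::-1]
        hits = set(g.choice(genes, size=7, replace=False).tolist())
        es = gsea_es(genes, weights, hits, exponent=0.0)
        es_rev = gsea_es(genes[::-1], weights[::-1], hits, exponent=0.0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_score_bounded_in_unit_interval(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(5, 80))
        genes = [f"g{i}" for i in range(n)]
        weights = g.normal(size=n) * float(g.integers(1, 10))
        k = int(g.integers(1, n))
        hits = set(g.choice(genes, size=k, replace=False).tolist())
        es = gsea_es(genes, weights, hits, exponent=float(g.choice([0.0, 1.0])))
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_empty_and_full_hit_sets_rejected(self):
        genes = ["a", "b", "c"]
        with pytest.raises(InvalidInputError):
            gsea_es(genes, [1, 1, 1], set())
        with pytest.raises(InvalidInputError):
            gsea_es(genes, [1, 1, 1], set(genes))


class TestMRA:
    def test_planted_regulon_has_smallest_adjusted_p(self, small_truth, perturbed_cohort):
        sig = compute_signature(perturbed_cohort)
        regs = regulons_from_truth(small_truth)
        recs = mra(regs, sig, n_perm=500, seed=11)
        best = min(recs, key=lambda r: r.p_adj)
        assert best.tf == "TF000"
        assert best.p_adj <= 0.05

    def test_identical_inputs_identical_records(self, small_truth, perturbed_cohort):
        sig = compute_signature(perturbed_cohort)
        regs = regulons_from_truth(small_truth)
        a = mra(regs, sig, n_perm=200, seed=5)
        b = mra(list(reversed(regs)), sig, n_perm=200, seed=5)
        assert [r.__dict__ for r in a] == [r.__dict__ for r in b]

    def test_pvalues_never_zero_and_adjustment_monotone(self, small_truth, perturbed_cohort):
        sig = compute_signature(perturbed_cohort)
        recs = mra(regulons_from_truth(small_truth), sig, n_perm=200, seed=6)
        assert all(r.p_perm > 0 for r in recs)
        assert all(r.p_adj >= r.p_perm - 1e-15 for r in recs)
        order_p = np.argsort([r.p_perm for r in recs], kind="stable")
        padj_sorted = np.asarray([r.p_adj for r in recs])[order_p]
        assert (np.diff(padj_sorted) >= -1e-15).all()

    def test_targets_absent_from_signature_are_dropped(self):
        sig = _signature({f"g{i}": 10 - i for i in range(10)})
        reg = _regulon("T", pos=("g1", "g2", "g3", "g4", "g5", "phantom"))
        recs = mra([reg], sig, n_perm=100, min_size=5)
        assert len(recs) == 1

    def test_regulon_below_min_size_skipped(self):
        sig = _signature({f"g{i}": 10 - i for i in range(10)})
        reg = _regulon("T", pos=("g1", "g2"))
        assert mra([reg], sig, n_perm=100, min_size=5) == []


class TestTwoTailed:
    def test_split_matches_stored_signs(self, rng):
        pos = [f"p{i}" for i in range(6)]
        neg = [f"n{i}" for i in range(4)]
        a, b = split_regulon(_regulon("T", pos=pos, neg=neg))
        assert a == set(pos) and b == set(neg)

    def test_all_positive_regulon_has_empty_negative_tail(self):
        a, b = split_regulon(_regulon("T", pos=("x", "y", "z")))
        assert b == set()
        assert len(a) == 3

    def test_maximal_separation_gives_positive_differential(self):
        logfc = {f"g{i:02d}": 10.0 - i for i in range(20)}
        sig = _signature(logfc)
        reg = _regulon(
            "T",
            pos=[f"g{i:02d}" for i in range(4)],      # top of the ranking
            neg=[f"g{i:02d}" for i in range(16, 20)],  # bottom
        )
        rec = two_tailed_gsea(reg, sig, n_perm=100, min_tail=2, seed=1)
        assert rec.es_a > 0 > rec.es_b
        assert rec.des > 0

    def test_exchanging_tails_negates_differential(self):
        logfc = {f"g{i:02d}": np.sin(i * 2.3) * (20 - i) for i in range(30)}
        sig = _signature(logfc)
        pos = [f"g{i:02d}" for i in (0, 3, 7, 11)]
        neg = [f"g{i:02d}" for i in (20, 23, 27, 29)]
        rec = two_tailed_gsea(_regulon("T", pos=pos, neg=neg), sig, n_perm=100,
                              min_tail=2, seed=2)
        rec_swapped = two_tailed_gsea(_regulon("T", pos=neg, neg=pos), sig,
                                      n_perm=100, min_tail=2, seed=2)
        assert rec_swapped.des == pytest.approx(-rec.des, abs=1e-12)
        assert rec_swapped.es_a == pytest.approx(rec.es_b, abs=1e-12)

    def test_repressed_regulon_called_repressed(self, small_truth, perturbed_cohort):
        sig = compute_signature(perturbed_cohort)
        planted = next(
            r for r in regulons_from_truth(small_truth) if r.tf == "TF000"
        )
        rec = two_tailed_gsea(planted, sig, n_perm=999, min_tail=3, seed=3)
        assert rec.des < 0
        assert rec.direction == REPRESSED

    def test_short_tail_yields_inconclusive_with_reason(self):
        sig = _signature({f"g{i}": float(10 - i) for i in range(10)})
        reg = _regulon("T", pos=("g1", "g2", "g3", "g4", "g5"), neg=("g6",))
        rec = two_tailed_gsea(reg, sig, n_perm=100, min_tail=5)
        assert rec.direction == INCONCLUSIVE
        assert "tail_below_min" in rec.reason

    def test_differential_bounds_and_consistency(self, small_truth, perturbed_cohort):
        sig = compute_signature(perturbed_cohort)
        recs = two_tailed_mra(
            regulons_from_truth(small_truth), sig, n_perm=200, min_tail=3, seed=4
        )
        for r in recs:
            assert -1 <= r.es_a <= 1 and -1 <= r.es_b <= 1
            assert r.des == pytest.approx(r.es_a - r.es_b, abs=1e-12)
            assert -2 <= r.des <= 2
            if r.direction == INDUCED:
                assert r.des > 0 and r.p_adj <= 0.05
            if r.direction == REPRESSED:
                assert r.des < 0 and r.p_adj <= 0.05


def _record(tf, net, sig, p_adj):
    return EnrichmentRecord(tf, net, sig, es=0.5, p_perm=p_adj, p_adj=p_adj)


class TestConsensus:
    COMBOS = [("tn1", "sig1"), ("tn1", "sig2"), ("tn2", "sig1"), ("tn2", "sig2")]

    def test_significant_in_all_four_is_standard(self):
        recs = [_record("A", n, s, 0.01) for n, s in self.COMBOS]
        report = consensus(recs, alpha=0.05, alpha_strict=0.001)
        assert report.standard_tfs == ["A"]
        assert report.stringent_tfs == []

    def test_three_of_four_is_not_consensus(self):
        recs = [_record("A", n, s, 0.01) for n, s in self.COMBOS[:3]]
        recs.append(_record("A", *self.COMBOS[3], 0.2))
        report = consensus(recs, alpha=0.05, alpha_strict=0.001)
        assert report.standard_tfs == []

    def test_stringent_implies_standard(self):
        recs = [_record("A", n, s, 0.0005) for n, s in self.COMBOS]
        recs += [_record("B", n, s, 0.02) for n, s in self.COMBOS]
        report = consensus(recs, alpha=0.05, alpha_strict=0.001)
        assert report.stringent_tfs == ["A"]
        assert set(report.stringent_tfs) <= set(report.standard_tfs)

    def test_missing_combination_counts_as_nonsignificant(self):
        recs = [_record("A", n, s, 0.001) for n, s in self.COMBOS]
        recs.append(_record("B", "tn1", "sig1", 0.001))
        report = consensus(recs)
        assert "B" not in report.standard_tfs
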