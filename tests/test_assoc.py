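"""Correlation statistic, binomial null, FDR cutoff, epistasis search,
SNP site classification and distances."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synassoc.annotate import ExonModel
from synassoc.assoc import (
    associate_all,
    classify_snp_site,
    correlation,
    explain_event,
    fdr_cutoff,
    genotype_phenotype_map,
    null_tail,
    snp_event_distance,
)
from synassoc.events import Event
from synassoc.variants import SnpRecord
from conftest import make_exon


def make_event(inter_vector, contig="c1", members=()):
    vec = np.concatenate([[0, 1], np.asarray(inter_vector, dtype=np.uint8)])
    return Event("e1", contig, list(members), vec)


class TestCorrelation:
    def test_full_agreement_is_one(self):
        e = np.ones(500, dtype=np.uint8)
        agreement, corr = correlation(e, e)
        assert (agreement, corr) == (500, 1.0)

    def test_chance_agreement_is_zero(self):
        e = np.zeros(500, dtype=np.uint8)
        s = np.concatenate([np.ones(250, np.uint8), np.zeros(250, np.uint8)])
        agreement, corr = correlation(e, s)
        assert (agreement, corr) == (250, 0.0)

    def test_anti_correlation_folds(self):
        # raw match count 125 of 500 folds to agreement 375, correlation 0.5
        e = np.zeros(500, dtype=np.uint8)
        s = np.concatenate([np.zeros(125, np.uint8), np.ones(375, np.uint8)])
        agreement, corr = correlation(e, s)
        assert (agreement, corr) == (375, 0.5)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            correlation([0, 1], [0, 1, 0])

    @given(st.integers(0, 2 ** 24 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_folding_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.integers(0, 2, 40)
        s = rng.integers(0, 2, 40)
        base = correlation(e, s)
        assert correlation(e, 1 - s) == base
        assert correlation(1 - e, s) == base
        assert correlation(1 - e, 1 - s) == base


class TestNullTail:
    def test_tail_at_zero_is_all_pairs(self):
        assert null_tail(500, 12345, 0.0) == 12345

    def test_tail_at_one_is_negligible(self):
        assert null_tail(500, 10 ** 6, 1.0) == pytest.approx(
            10 ** 6 * 2 * 0.5 ** 500, abs=1e-100)

    def test_small_case_matches_enumeration(self):
        # N=10, c=0.6 means agreement >= 8: enumerate all 2^10 outcomes
        count = 0
        for bits in itertools.product([0, 1], repeat=10):
            x = sum(bits)
            if max(x, 10 - x) >= 8:
                count += 1
        assert count == 112
        assert null_tail(10, 1024, 0.6) == pytest.approx(count)

    def test_monotone_non_increasing(self):
        tails = [null_tail(100, 1000, c) for c in np.linspace(0, 1, 21)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))


class TestFdrCutoff:
    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(42)
        x = rng.binomial(500, 0.5, size=10_000)
        null = (np.maximum(x, 500 - x) - 250) / 250
        obs = np.concatenate([null, np.ones(5)])
        cutoff = fdr_cutoff(obs, 500, alpha=0.05)
        assert cutoff < 1.0
        # recompute the FDR ratio directly at the returned cutoff
        observed = (obs >= cutoff - 1e-12).sum()
        assert null_tail(500, obs.size, cutoff) / observed <= 0.05
        assert all(v > cutoff for v in np.ones(5))

    def test_pure_null_flags_almost_nothing(self):
        rng = np.random.default_rng(7)
        x = rng.binomial(500, 0.5, size=10_000)
        null = (np.maximum(x, 500 - x) - 250) / 250
        cutoff = fdr_cutoff(null, 500, alpha=0.05)
        assert math.isinf(cutoff) or (null > cutoff).mean() <= 0.01

    def test_alpha_one_admits_everything(self):
        cutoff = fdr_cutoff([0.0, 0.1, 0.5], 500, alpha=1.0)
        assert cutoff == 0.0  # smallest achievable value

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            fdr_cutoff([], 500)


class TestAssociateAll:
    def test_perfect_snp_detected(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 2, size=(200, 5), dtype=np.uint8)
        ev = make_event(geno[:, 2])
        results, _ = associate_all([ev], geno,
                                   [SnpRecord("c1", i, "A", "G") for i in range(5)])
        perfect = [r.snp_index for r in results if r.perfect]
        assert perfect == [2]
        assert [r.correlation for r in results if r.perfect] == [1.0]

    def test_degenerate_event_excluded_from_cutoff(self, caplog):
        geno = np.random.default_rng(1).integers(0, 2, (100, 3), dtype=np.uint8)
        ev = make_event(np.zeros(100))
        with caplog.at_level("WARNING"):
            results, cutoff = associate_all([ev], geno,
                                            [SnpRecord("c1", i, "A", "G")
                                             for i in range(3)])
        assert "no variation" in caplog.text
        assert math.isinf(cutoff)
        assert len(results) == 3

    def test_permuted_genotypes_rarely_significant(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 2, size=(500, 1), dtype=np.uint8)
        ev = make_event(geno[:, 0])
        hits = 0
        for _ in range(100):
            perm = geno[rng.permutation(500)]
            _, corr = correlation(ev.intermediate_vector(), perm[:, 0])
            if corr > 0.244:
                hits += 1
        assert hits <= 5


class TestExplainEvent:
    def worked_example(self):
        """The two-SNP mapping AT/AA/GT -> alt phenotype, GA -> reference."""
        combos = [("AT", 1), ("AA", 1), ("GT", 1), ("GA", 0)]
        geno_rows, phen = [], []
        for (alleles, ph) in combos:
            for _ in range(25):
                geno_rows.append([1 if alleles[0] == "A" else 0,
                                  1 if alleles[1] == "T" else 0])
                phen.append(ph)
        geno = np.array(geno_rows, dtype=np.uint8)
        snps = [SnpRecord("c1", 10, "G", "A"), SnpRecord("c1", 20, "A", "T")]
        return make_event(phen), geno, snps

    def test_two_snp_mapping_completely_explains(self):
        ev, geno, snps = self.worked_example()
        assert explain_event(ev, geno, [0, 1]) == (0, 1)
        gmap = genotype_phenotype_map(ev, geno, snps, (0, 1))
        assert gmap == {"AT": {1}, "AA": {1}, "GT": {1}, "GA": {0}}

    def test_removing_either_snp_leaves_it_unexplained(self):
        ev, geno, _ = self.worked_example()
        assert explain_event(ev, geno, [0], max_k=1) is None
        assert explain_event(ev, geno, [1], max_k=1) is None

    def test_perfect_snp_explains_alone(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 2, (100, 4), dtype=np.uint8)
        ev = make_event(geno[:, 1])
        assert explain_event(ev, geno, [0, 1, 2, 3]) == (1,)

    def test_ambiguous_genotype_combination_blocks_explanation(self):
        # one genotype tuple observed with both phenotypes
        geno = np.array([[0, 0], [0, 0], [1, 0], [1, 1]], dtype=np.uint8)
        ev = make_event([0, 1, 0, 1])
        assert explain_event(ev, geno, [0, 1], max_k=2) is None

    def test_candidate_cap_truncates_by_correlation(self, caplog):
        rng = np.random.default_rng(8)
        geno = rng.integers(0, 2, (60, 10), dtype=np.uint8)
        ev = make_event(geno[:, 9])
        corrs = {i: i / 10 for i in range(10)}
        with caplog.at_level("WARNING"):
            got = explain_event(ev, geno, list(range(10)),
                                correlations=corrs, candidate_cap=3)
        assert "truncated" in caplog.text
        assert got == (9,)

    def test_returned_subsets_verified_by_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            geno = rng.integers(0, 2, (40, 5), dtype=np.uint8)
            phen = (geno[:, 0] & geno[:, 3]).astype(np.uint8)
            ev = make_event(phen)
            got = explain_event(ev, geno, [0, 1, 2, 3, 4])
            assert got is not None
            mapping = {}
            ok = True
            for row, p in zip(geno[:, list(got)], phen):
                sig = tuple(row)
                if mapping.setdefault(sig, p) != p:
                    ok = False
            assert ok
            # minimality: no strictly smaller subset explains
            for k in range(1, len(got)):
                for sub in itertools.combinations(range(5), k):
                    mapping = {}
                    single = True
                    for row, p in zip(geno[:, list(sub)], phen):
                        if mapping.setdefault(tuple(row), p) != p:
                            single = False
                    assert not single


class TestClassifySnpSite:
    def gene(self, contig="c1"):
        return [
            ExonModel(contig, "initial", 100, 200, "+", gene_id="g1"),
            ExonModel(contig, "terminal", 300, 400, "+", gene_id="g1"),
        ]

    def snp(self, pos, contig="c1"):
        return SnpRecord(contig, pos, "A", "G")

    @pytest.mark.parametrize("pos, expected", [
        (100, "start"), (102, "start"),        # first 3 bp of the gene span
        (397, "stop"), (399, "stop"),          # last 3 bp
        (200, "splice_donor"), (204, "splice_donor"),
        (295, "splice_acceptor"), (299, "splice_acceptor"),
        (150, "exon"), (350, "exon"),
        (250, "intron"),
        (50, "intergenic"), (500, "intergenic"),
    ])
    def test_plus_strand_classes(self, pos, expected):
        assert classify_snp_site(self.snp(pos), self.gene(), self.gene()) == expected

    def test_minus_strand_windows_are_strand_aware(self):
        gene = [
            ExonModel("c1", "terminal", 100, 200, "-", gene_id="g1"),
            ExonModel("c1", "initial", 300, 400, "-", gene_id="g1"),
        ]
        assert classify_snp_site(self.snp(399), gene, gene) == "start"
        assert classify_snp_site(self.snp(100), gene, gene) == "stop"
        # intron 5' end on a minus-strand gene is its highest coordinate
        assert classify_snp_site(self.snp(299), gene, gene) == "splice_donor"
        assert classify_snp_site(self.snp(200), gene, gene) == "splice_acceptor"

    def test_hierarchy_across_genomes(self):
        # start codon in one genome, intron in the other -> start
        intronic_gene = [
            ExonModel("c1", "initial", 0, 50, "+", gene_id="g2"),
            ExonModel("c1", "terminal", 150, 250, "+", gene_id="g2"),
        ]
        assert classify_snp_site(self.snp(100), self.gene(), intronic_gene) == "start"

    def test_intergenic_when_outside_all_genes(self):
        assert classify_snp_site(self.snp(1000), self.gene(), self.gene()) \
            == "intergenic"


class TestSnpEventDistance:
    def event_with_members(self):
        keys = [("c1", "single", 100, 200, "+"), ("c1", "single", 400, 500, "+")]
        return Event("e", "c1", [(k, 1) for k in keys],
                     np.array([0, 1], dtype=np.uint8))

    def test_inside_member_exon_is_zero(self):
        assert snp_event_distance(SnpRecord("c1", 150, "A", "G"),
                                  self.event_with_members()) == 0

    def test_nearby_gap_measured_to_nearest_boundary(self):
        ev = self.event_with_members()
        assert snp_event_distance(SnpRecord("c1", 89, "A", "G"), ev) == 11
        assert snp_event_distance(SnpRecord("c1", 210, "A", "G"), ev) == 11

    def test_other_contig_is_unlinked(self):
        assert snp_event_distance(SnpRecord("c9", 150, "A", "G"),
                                  self.event_with_members()) is None
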