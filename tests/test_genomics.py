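"""Loop classification, span metrics, expression classes, statistics.

Fisher exact and Kolmogorov-Smirnov are checked against independent
oracles: full hypergeometric enumeration over all tables with fixed
margins, and explicit ECDF supremum enumeration plus label permutation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from loopscore.genomics import (
    ClassifiedLoop,
    ExpressionContrasts,
    assign_expression_class,
    assign_expression_classes,
    classify_ctcf_loop,
    classify_ep_loop,
    fisher_exact_2x2,
    ks_two_sample,
    longest_loop_per_gene,
    loop_span,
    mean_loop_span_per_gene,
    promoter_binding_enrichment,
    span_table,
)
from loopscore.intervals_io import (
    DEStatus,
    Enhancer,
    GeneRecord,
    GenomicInterval,
    Loop,
    Peak,
)


# ---------------------------------------------------------------- oracles

def fisher_oracle(table):
    """Two-tailed p by summing hypergeometric probabilities of all tables
    with the observed margins whose probability <= the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


def ks_d_oracle(a, b):
    """Supremum ECDF distance by enumeration over all pooled points."""
    pts = np.concatenate([a, b])
    best = 0.0
    for x in pts:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


# ----------------------------------------------------------- classification

ANCHOR1 = GenomicInterval("chr1", 100_000, 110_000)
ANCHOR2 = GenomicInterval("chr1", 500_000, 510_000)
LOOP = Loop(ANCHOR1, ANCHOR2)


class TestLoopClassification:
    def test_ctcf_peak_in_anchor(self):
        assert classify_ctcf_loop(LOOP, [Peak(GenomicInterval("chr1", 104_000, 104_500), "CTCF")])
        assert not classify_ctcf_loop(LOOP, [Peak(GenomicInterval("chr1", 200_000, 201_000), "CTCF")])
        # 1 bp overlap at the anchor boundary counts
        assert classify_ctcf_loop(LOOP, [Peak(GenomicInterval("chr1", 509_999, 511_000), "CTCF")])

    def test_ep_classification_rules(self):
        gene = GeneRecord("g", GenomicInterval("chr1", 105_000, 105_001))
        inducible = [Enhancer(GenomicInterval("chr1", 505_000, 505_600), True)]
        constitutive = [Enhancer(GenomicInterval("chr1", 505_000, 505_600), False)]
        assert classify_ep_loop(LOOP, gene, inducible, require_inducible=True)
        assert not classify_ep_loop(LOOP, gene, constitutive, require_inducible=True)
        assert classify_ep_loop(LOOP, gene, constitutive, require_inducible=False)
        outside = GeneRecord("g2", GenomicInterval("chr1", 300_000, 300_001))
        assert not classify_ep_loop(LOOP, outside, inducible, require_inducible=False)

    @pytest.mark.parametrize("a1, a2, expected", [
        ((100, 200), (500, 700), 450),
        ((0, 10_000), (1_000_000, 1_010_000), 1_000_000),
    ])
    def test_loop_span_midpoint_distance(self, a1, a2, expected):
        loop = Loop(GenomicInterval("chr1", *a1), GenomicInterval("chr1", *a2))
        assert loop_span(loop) == expected

    def test_trans_span_rejected(self):
        loop = Loop(GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 500, 600))
        with pytest.raises(ValueError):
            loop_span(loop)

    def test_span_invariant_under_symmetric_widening(self):
        base = Loop(GenomicInterval("chr1", 1000, 2000), GenomicInterval("chr1", 9000, 10_000))
        widened = Loop(GenomicInterval("chr1", 500, 2500), GenomicInterval("chr1", 8500, 10_500))
        assert loop_span(base) == loop_span(widened)


class TestPerGeneSpans:
    def _gene(self):
        return GeneRecord("g", GenomicInterval("chr1", 105_000, 105_001))

    def _classified(self, spans, gene_id="g", **kw):
        out = []
        for s in spans:
            a1 = GenomicInterval("chr1", 100_000, 110_000)
            a2 = GenomicInterval("chr1", 100_000 + s, 110_000 + s)
            out.append(ClassifiedLoop(Loop(a1, a2), s, kw.get("is_ctcf", True),
                                      kw.get("is_ep", False), gene_id))
        return out

    def test_longest_and_mean(self):
        gene = self._gene()
        loops = self._classified([50_000, 400_000])
        assert longest_loop_per_gene(gene, loops, "all") == 400_000
        assert mean_loop_span_per_gene(gene, loops, "all") == 225_000
        assert longest_loop_per_gene(gene, self._classified([50_000]), "all") == 50_000

    def test_no_loops_returns_none(self):
        gene = self._gene()
        assert longest_loop_per_gene(gene, [], "all") is None
        assert mean_loop_span_per_gene(gene, [], "all") is None

    def test_span_table_inclusion_rules(self):
        gene_with = self._gene()
        gene_without = GeneRecord("g2", GenomicInterval("chr1", 900_000, 900_001))
        loops = self._classified([200_000])
        for stat in ("longest", "mean"):
            tab = span_table([gene_with, gene_without], loops, "all", stat)
            row = tab.set_index("gene_id")
            assert row.loc["g", "span"] == 200_000
            assert row.loc["g2", "span"] == 0 and row.loc["g2", "included"]
            assert not row.loc["g2", "has_loop"]
        tab = span_table([gene_with, gene_without], loops, "enhancer_promoter")
        row = tab.set_index("gene_id")
        assert not row.loc["g", "included"]  # loop is not enhancer-promoter
        assert not row.loc["g2", "included"]

    def test_filters_select_loop_classes(self):
        gene = self._gene()
        ctcf_only = self._classified([100_000], is_ctcf=True, is_ep=False)
        ep_only = self._classified([300_000], is_ctcf=False, is_ep=True)
        loops = ctcf_only + ep_only
        assert longest_loop_per_gene(gene, loops, "all") == 300_000
        assert longest_loop_per_gene(gene, loops, "ctcf") == 100_000
        assert longest_loop_per_gene(gene, loops, "enhancer_promoter") == 300_000


# ------------------------------------------------------- expression classes

CONTRASTS = ExpressionContrasts(genotype=("geno_TTX", "geno_KCl6h"),
                                induction=("ind_1h", "ind_6h"))


def gene_with(geno_ttx, geno_kcl, ind1=(0.0, 0.5, True), ind2=(0.0, 0.5, True),
              gene_id="g"):
    de = {
        "geno_TTX": DEStatus(*geno_ttx),
        "geno_KCl6h": DEStatus(*geno_kcl),
        "ind_1h": DEStatus(*ind1),
        "ind_6h": DEStatus(*ind2),
    }
    return GeneRecord(gene_id, GenomicInterval("chr1", 1000, 1001), "other", de)


class TestExpressionClasses:
    def test_downregulated_lrg(self):
        g = gene_with((-1.5, 0.01, True), (-2.0, 0.02, True))
        a = assign_expression_class(g, CONTRASTS, [], ["g"])
        assert a.expression_class == "downregulated_LRG"

    def test_lrg_deregulated_in_one_condition_excluded(self):
        g = gene_with((-1.5, 0.01, True), (-0.1, 0.5, True))
        a = assign_expression_class(g, CONTRASTS, [], ["g"])
        assert a.expression_class == "excluded"

    def test_downregulation_requires_negative_fold_change(self):
        g = gene_with((1.5, 0.01, True), (2.0, 0.02, True))  # up, not down
        a = assign_expression_class(g, CONTRASTS, [], ["g"])
        assert a.expression_class == "excluded"

    def test_non_deregulated_lrg(self):
        g = gene_with((0.1, 0.4, True), (-0.1, 0.8, True))
        a = assign_expression_class(g, CONTRASTS, [], ["g"])
        assert a.expression_class == "non_deregulated_LRG"

    def test_curated_ieg_label_wins(self):
        g = gene_with((-1.5, 0.01, True), (-2.0, 0.02, True))
        a = assign_expression_class(g, CONTRASTS, ["g"], [])
        assert a.expression_class == "IEG"

    def test_constitutive_requires_expression_and_flat_induction(self):
        g = gene_with((0.0, 0.5, True), (0.0, 0.5, True),
                      ind1=(0.2, 0.3, True), ind2=(-0.1, 0.4, True))
        a = assign_expression_class(g, CONTRASTS, [], [])
        assert a.expression_class == "constitutive"

    def test_inducible_needs_p_and_fold_change(self):
        g = gene_with((0.0, 0.5, True), (0.0, 0.5, True),
                      ind1=(2.0, 0.001, True))
        assert assign_expression_class(g, CONTRASTS, [], []).expression_class == "inducible"
        weak = gene_with((0.0, 0.5, True), (0.0, 0.5, True),
                         ind1=(0.5, 0.001, True))
        assert assign_expression_class(weak, CONTRASTS, [], []).expression_class == "other"

    def test_missing_contrast_named(self):
        g = gene_with((0.0, 0.5, True), (0.0, 0.5, True))
        bad = ExpressionContrasts(("geno_TTX", "geno_missing"), ("ind_1h", "ind_6h"))
        with pytest.raises(KeyError, match="geno_missing"):
            assign_expression_class(g, bad, [], [])

    def test_gene_in_both_lists_rejected(self):
        g = gene_with((0.0, 0.5, True), (0.0, 0.5, True))
        with pytest.raises(ValueError, match="both"):
            assign_expression_class(g, CONTRASTS, ["g"], ["g"])

    def test_partition_property(self, rng):
        genes = []
        for k in range(60):
            geno = (float(rng.normal()), float(rng.uniform()), True)
            geno2 = (float(rng.normal()), float(rng.uniform()), True)
            ind1 = (float(rng.normal(1, 1)), float(rng.uniform()), bool(rng.random() < 0.9))
            ind2 = (float(rng.normal(1, 1)), float(rng.uniform()), bool(rng.random() < 0.9))
            genes.append(gene_with(geno, geno2, ind1, ind2, gene_id=f"g{k}"))
        ieg = [g.gene_id for g in genes[:10]]
        lrg = [g.gene_id for g in genes[10:30]]
        assignments = assign_expression_classes(genes, CONTRASTS, ieg, lrg)
        assert len(assignments) == len(genes)
        ids = [a.gene_id for a in assignments]
        assert len(set(ids)) == len(ids)
        assert all(a.expression_class in {
            "IEG", "downregulated_LRG", "non_deregulated_LRG", "excluded",
            "constitutive", "inducible", "other"} for a in assignments)
        assert all(a.reason for a in assignments)


# ----------------------------------------------------------------- KS test

class TestKSTwoSample:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = ks_two_sample([1, 2], [3, 4])
        assert res.statistic == 1.0

    def test_worked_example(self):
        res = ks_two_sample([1, 2, 3], [1.5, 2.5])
        assert res.statistic == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_d_matches_ecdf_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 40))
        b = rng.normal(loc=rng.normal(), size=rng.integers(3, 40))
        res = ks_two_sample(a, b)
        assert res.statistic == pytest.approx(ks_d_oracle(a, b), abs=1e-12)

    def test_permutation_agrees_with_exact(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = rng.normal(0.5, size=40)
        exact = ks_two_sample(a, b, method="exact")
        perm = ks_two_sample(a, b, method="permutation", n_perm=20_000,
                             rng=np.random.default_rng(1))
        se = np.sqrt(exact.pvalue * (1 - exact.pvalue) / 20_000)
        assert abs(perm.pvalue - exact.pvalue) < 4 * se + 1e-4


# ------------------------------------------------------------ Fisher exact

class TestFisherExact:
    def test_no_association(self):
        res = fisher_exact_2x2([[10, 10], [10, 10]])
        assert res.odds_ratio == 1.0
        assert res.pvalue == pytest.approx(1.0)

    def test_strong_association_enumeration(self):
        res = fisher_exact_2x2([[9, 1], [1, 9]])
        assert res.odds_ratio == 81.0
        assert res.pvalue == pytest.approx(202 / 184_756)

    def test_infinite_odds_ratio(self):
        res = fisher_exact_2x2([[5, 0], [0, 5]])
        assert math.isinf(res.odds_ratio)
        assert res.pvalue == pytest.approx(2 / math.comb(10, 5))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [2, 3]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 1], [2, 3]])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hypergeometric_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 30, size=(2, 2))
        res = fisher_exact_2x2(t)
        assert res.pvalue == pytest.approx(fisher_oracle(t), abs=1e-10)


class TestPromoterEnrichment:
    def _gene(self, gid, tss):
        return GeneRecord(gid, GenomicInterval("chr1", tss, tss + 1))

    def test_hand_enumerated_table(self):
        interest = [self._gene("a", 10_000), self._gene("b", 50_000),
                    self._gene("c", 90_000)]
        background = [self._gene("d", 200_000), self._gene("e", 300_000)]
        peaks = [Peak(GenomicInterval("chr1", 9_000, 9_500), "CTCF"),     # in a's window
                 Peak(GenomicInterval("chr1", 51_900, 52_100), "CTCF"),   # in b's window
                 Peak(GenomicInterval("chr1", 240_000, 241_000), "CTCF")]  # nobody's
        res = promoter_binding_enrichment(interest, background, peaks,
                                          promoter_halfwidth=2000)
        assert res.table == ((2, 1), (0, 2))

    def test_extreme_tables(self):
        interest = [self._gene("a", 10_000)]
        background = [self._gene("d", 200_000)]
        bound_all = [Peak(GenomicInterval("chr1", 9_999, 10_001), "CTCF")]
        res = promoter_binding_enrichment(interest, background, bound_all)
        assert math.isinf(res.odds_ratio)

    def test_identical_rates_or_one(self):
        interest = [self._gene("a", 10_000), self._gene("b", 50_000)]
        background = [self._gene("d", 200_000), self._gene("e", 300_000)]
        peaks = [Peak(GenomicInterval("chr1", 10_000, 10_100), "C"),
                 Peak(GenomicInterval("chr1", 200_000, 200_100), "C")]
        res = promoter_binding_enrichment(interest, background, peaks)
        assert res.odds_ratio == 1.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            promoter_binding_enrichment([self._gene("a", 100)], [], [])

    def test_overlapping_sets_rejected(self):
        g = self._gene("a", 100)
        with pytest.raises(ValueError):
            promoter_binding_enrichment([g], [g], [])
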