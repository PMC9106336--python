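"""Loop classification, span metrics, expression classes, and statistics.

This layer carries the headline comparison: whether genes that lose
expression under cohesin depletion form longer chromatin loops. Loops are
classified by anchor content (CTCF peak in an anchor; TSS in one anchor
with an enhancer in the other), spans are midpoint-to-midpoint distances,
gene expression classes are assigned from differential-expression tables
under explicit adjusted-p / fold-change rules, and the group comparisons
use two-sample Kolmogorov-Smirnov and two-tailed Fisher exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals_io import Enhancer, GeneRecord, GenomicInterval, Loop, Peak, midpoint, overlaps

__all__ = [
    "ClassifiedLoop",
    "GeneClassAssignment",
    "ExpressionContrasts",
    "KSResult",
    "FisherResult",
    "EnrichmentResult",
    "classify_ctcf_loop",
    "classify_ep_loop",
    "loop_span",
    "classify_loops",
    "longest_loop_per_gene",
    "mean_loop_span_per_gene",
    "span_table",
    "assign_expression_class",
    "assign_expression_classes",
    "ks_two_sample",
    "fisher_exact_2x2",
    "promoter_binding_enrichment",
]

LoopFilter = Literal["all", "ctcf", "enhancer_promoter"]


@dataclass(frozen=True)
class ClassifiedLoop:
    """One (loop, gene) classification record.

    A loop touching the TSSs of several genes yields one record per gene;
    a loop anchored at no TSS yields a single record with ``gene_id``
    None (usable for CTCF statistics but not per-gene spans).
    """

    loop: Loop
    span: int
    is_ctcf: bool
    is_enhancer_promoter: bool
    gene_id: str | None = None
    enhancer_inducible: bool = False

    def __post_init__(self) -> None:
        if self.is_enhancer_promoter and self.gene_id is None:
            raise ValueError("enhancer-promoter classification requires a gene")


@dataclass(frozen=True)
class GeneClassAssignment:
    gene_id: str
    expression_class: str  # IEG | downregulated_LRG | non_deregulated_LRG |
    # constitutive | inducible | other | excluded
    reason: str = ""


@dataclass(frozen=True)
class ExpressionContrasts:
    """Names of the DE contrasts the class rules read.

    ``genotype`` are the depleted-vs-control contrasts under silenced
    (TTX) and 6 hr depolarized (KCl) conditions; ``induction`` are the
    stimulation-vs-silenced contrasts in wild type.
    """

    genotype: tuple[str, str]
    induction: tuple[str, str]


class KSResult(NamedTuple):
    statistic: float
    pvalue: float


class FisherResult(NamedTuple):
    odds_ratio: float
    pvalue: float


class EnrichmentResult(NamedTuple):
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    pvalue: float


def classify_ctcf_loop(loop: Loop, ctcf_peaks: Sequence[Peak]) -> bool:
    """True iff at least one peak overlaps either anchor (partial counts)."""
    return any(overlaps(p.interval, loop.anchor1) or overlaps(p.interval, loop.anchor2)
               for p in ctcf_peaks)


def classify_ep_loop(loop: Loop, gene: GeneRecord, enhancers: Sequence[Enhancer],
                     require_inducible: bool = True) -> bool:
    """True iff the gene's TSS lies in one anchor and the other anchor
    holds a qualifying enhancer (activity-induced only when
    ``require_inducible``; any enhancer otherwise)."""
    if overlaps(gene.tss, loop.anchor1):
        other = loop.anchor2
    elif overlaps(gene.tss, loop.anchor2):
        other = loop.anchor1
    else:
        return False
    for e in enhancers:
        if overlaps(e.interval, other) and (e.inducible or not require_inducible):
            return True
    return False


def loop_span(loop: Loop) -> int:
    """Genomic distance between the midpoints of the two anchors (bp)."""
    if not loop.is_cis:
        raise ValueError("loop span is undefined for trans loops")
    return abs(midpoint(loop.anchor2) - midpoint(loop.anchor1))


def classify_loops(loops: Sequence[Loop], ctcf_peaks: Sequence[Peak],
                   genes: Sequence[GeneRecord], enhancers: Sequence[Enhancer],
                   require_inducible_enhancer: bool = True) -> list[ClassifiedLoop]:
    """Classify every loop against peaks, gene TSSs and enhancers."""
    out: list[ClassifiedLoop] = []
    for lp in loops:
        span = loop_span(lp)
        is_ctcf = classify_ctcf_loop(lp, ctcf_peaks)
        touched = [g for g in genes
                   if overlaps(g.tss, lp.anchor1) or overlaps(g.tss, lp.anchor2)]
        if not touched:
            out.append(ClassifiedLoop(lp, span, is_ctcf, False))
            continue
        for g in touched:
            is_ep = classify_ep_loop(lp, g, enhancers, require_inducible_enhancer)
            inducible = is_ep and classify_ep_loop(lp, g, enhancers, True)
            out.append(ClassifiedLoop(lp, span, is_ctcf, is_ep, g.gene_id, inducible))
    return out


def _gene_spans(gene: GeneRecord, loops: Iterable[ClassifiedLoop],
                loop_filter: LoopFilter) -> list[int]:
    spans = []
    for cl in loops:
        if cl.gene_id != gene.gene_id:
            continue
        if loop_filter == "ctcf" and not cl.is_ctcf:
            continue
        if loop_filter == "enhancer_promoter" and not cl.is_enhancer_promoter:
            continue
        spans.append(cl.span)
    return spans


def longest_loop_per_gene(gene: GeneRecord, loops: Iterable[ClassifiedLoop],
                          loop_filter: LoopFilter = "all") -> int | None:
    """Longest qualifying loop span for the gene, or None without loops.

    Callers building group comparisons encode loop-less genes as span 0
    for the all/CTCF analyses and drop them for enhancer-promoter
    analyses (see ``span_table``).
    """
    spans = _gene_spans(gene, loops, loop_filter)
    return max(spans) if spans else None


def mean_loop_span_per_gene(gene: GeneRecord, loops: Iterable[ClassifiedLoop],
                            loop_filter: LoopFilter = "all") -> float | None:
    """Mean qualifying loop span for the gene, or None without loops."""
    spans = _gene_spans(gene, loops, loop_filter)
    return float(np.mean(spans)) if spans else None


def span_table(genes: Sequence[GeneRecord], loops: Sequence[ClassifiedLoop],
               loop_filter: LoopFilter = "all",
               statistic: str = "longest") -> pd.DataFrame:
    """Per-gene span table applying the inclusion rule for loop-less genes.

    Genes without qualifying loops enter with span 0 (flagged
    ``has_loop=False``) except under the enhancer-promoter filter, where
    they are excluded (``included=False``); loops shorter than the
    resolution of loop calling cannot be recorded, so zero stands for
    "no detectable loop".
    """
    if statistic not in {"longest", "mean"}:
        raise ValueError("statistic must be 'longest' or 'mean'")
    fn = longest_loop_per_gene if statistic == "longest" else mean_loop_span_per_gene
    rows = []
    for g in genes:
        span = fn(g, loops, loop_filter)
        has_loop = span is not None
        included = has_loop or loop_filter != "enhancer_promoter"
        rows.append({
            "gene_id": g.gene_id,
            "class_label": g.class_label,
            "span": float(span) if has_loop else 0.0,
            "has_loop": has_loop,
            "included": included,
        })
    return pd.DataFrame(rows)


def assign_expression_class(gene: GeneRecord, contrasts: ExpressionContrasts,
                            ieg_genes: Iterable[str], lrg_genes: Iterable[str],
                            alpha: float = 0.05,
                            induction_lfc: float = 1.0) -> GeneClassAssignment:
    """Assign one mutually exclusive expression class from the DE table.

    Curated IEG/LRG membership is an input. Within LRGs: downregulated
    iff adj_p < alpha with negative log2FC in both genotype contrasts;
    non-deregulated iff adj_p > alpha in both; deregulated in exactly one
    condition -> excluded. Non-ARG genes: constitutive iff expressed with
    adj_p >= alpha in both induction contrasts; inducible iff adj_p <
    alpha and log2FC >= induction_lfc in either induction contrast.
    """
    ieg_set, lrg_set = set(ieg_genes), set(lrg_genes)
    if gene.gene_id in ieg_set and gene.gene_id in lrg_set:
        raise ValueError(f"gene {gene.gene_id} appears in both IEG and LRG lists")
    for name in (*contrasts.genotype, *contrasts.induction):
        if name not in gene.de_status:
            raise KeyError(f"gene {gene.gene_id} missing contrast {name!r}")

    if gene.gene_id in ieg_set:
        return GeneClassAssignment(gene.gene_id, "IEG", "curated IEG")
    if gene.gene_id in lrg_set:
        g1, g2 = (gene.de_status[c] for c in contrasts.genotype)
        down = [(st.adj_p < alpha and st.log2fc < 0) for st in (g1, g2)]
        nondereg = [st.adj_p > alpha for st in (g1, g2)]
        if all(down):
            return GeneClassAssignment(gene.gene_id, "downregulated_LRG",
                                       "adj_p < alpha with negative log2FC in both "
                                       "genotype contrasts")
        if all(nondereg):
            return GeneClassAssignment(gene.gene_id, "non_deregulated_LRG",
                                       "adj_p > alpha in both genotype contrasts")
        return GeneClassAssignment(gene.gene_id, "excluded",
                                   "deregulated in one condition but not both")
    ind = [gene.de_status[c] for c in contrasts.induction]
    if any(st.adj_p < alpha and st.log2fc >= induction_lfc for st in ind):
        return GeneClassAssignment(gene.gene_id, "inducible",
                                   "induced in at least one stimulation contrast")
    if all(st.adj_p >= alpha for st in ind) and all(st.expressed for st in ind):
        return GeneClassAssignment(gene.gene_id, "constitutive",
                                   "expressed, no significant induction response")
    return GeneClassAssignment(gene.gene_id, "other",
                               "not expressed or intermediate induction response")


def assign_expression_classes(genes: Sequence[GeneRecord],
                              contrasts: ExpressionContrasts,
                              ieg_genes: Iterable[str], lrg_genes: Iterable[str],
                              alpha: float = 0.05,
                              induction_lfc: float = 1.0) -> list[GeneClassAssignment]:
    ieg_set, lrg_set = set(ieg_genes), set(lrg_genes)
    return [assign_expression_class(g, contrasts, ieg_set, lrg_set, alpha,
                                    induction_lfc) for g in genes]


def ks_two_sample(a: Sequence[float], b: Sequence[float],
                  method: str = "asymp", n_perm: int = 10_000,
                  rng: np.random.Generator | None = None) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum ECDF distance. ``method`` selects the p-value:
    "asymp" (asymptotic Kolmogorov distribution at effective
    n = |a||b| / (|a| + |b|), the default), "exact" (full enumeration of
    the permutation distribution, preferable at small n), or
    "permutation" (Monte Carlo with ``n_perm`` label permutations).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method in {"asymp", "exact"}:
        res = stats.ks_2samp(a, b, method=method)
        return KSResult(float(res.statistic), float(res.pvalue))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    d_obs = float(stats.ks_2samp(a, b).statistic)
    if rng is None:
        rng = np.random.default_rng()
    n, m = a.size, b.size
    labels = np.zeros(n + m, dtype=np.float32)
    labels[:n] = 1.0
    tiled = rng.permuted(np.tile(labels, (n_perm, 1)), axis=1)
    ca = np.cumsum(tiled, axis=1)
    ranks = np.arange(1, n + m + 1, dtype=np.float32)
    d = np.abs(ca / n - (ranks - ca) / m).max(axis=1)
    p = (np.count_nonzero(d >= d_obs - 1e-12) + 1) / (n_perm + 1)
    return KSResult(d_obs, float(p))


def fisher_exact_2x2(table: Sequence[Sequence[float]]) -> FisherResult:
    """Two-tailed Fisher exact test on a 2x2 count table.

    Odds ratio is the sample OR (a*d)/(b*c), infinite when b*c = 0 with
    a*d > 0; the two-tailed p sums hypergeometric probabilities of all
    tables (at fixed margins) no more likely than the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    if np.any(t != np.floor(t)):
        raise ValueError("table entries must be integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table margins must be positive")
    (a, b), (c, d) = t
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(odds, float(p))


def promoter_binding_enrichment(genes_of_interest: Sequence[GeneRecord],
                                background_genes: Sequence[GeneRecord],
                                peaks: Sequence[Peak],
                                promoter_halfwidth: int = 2000) -> EnrichmentResult:
    """Fisher enrichment of peak binding at promoters of a gene set.

    A promoter is "bound" iff at least one peak overlaps
    [TSS - halfwidth, TSS + halfwidth) (clipped at zero). Gene sets must
    be disjoint; background must be non-empty.
    """
    if not background_genes:
        raise ValueError("background gene set is empty")
    interest_ids = {g.gene_id for g in genes_of_interest}
    if interest_ids & {g.gene_id for g in background_genes}:
        raise ValueError("gene sets must be disjoint")

    def bound(gene: GeneRecord) -> bool:
        tss = gene.tss.start
        prom = GenomicInterval(gene.tss.chrom, max(tss - promoter_halfwidth, 0),
                               tss + promoter_halfwidth)
        return any(overlaps(p.interval, prom) for p in peaks)

    a = sum(bound(g) for g in genes_of_interest)
    b = len(genes_of_interest) - a
    c = sum(bound(g) for g in background_genes)
    d = len(background_genes) - c
    table = ((a, b), (c, d))
    res = fisher_exact_2x2(table)
    return EnrichmentResult(table, res.odds_ratio, res.pvalue)
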