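"""Synthetic 5C and loop-genomics inputs with planted, recoverable structure.

Two generators live here. The contact generator emulates a multi-replicate,
multi-condition 5C experiment over one designed region: restriction-like
fragments, double-alternating primers, power-law distance decay with
per-primer multiplicative biases, negative-binomial counting noise,
planted constitutive (CTCF-anchored) and inducible (enhancer-promoter)
loops whose enrichment varies by condition, and PCR-bias spike pairs. The
fixture generator emits gene/loop/peak/enhancer/DE tables in which gene
classes carry configurable loop-span distributions, so the downstream
span-versus-dysregulation statistics can be checked by parameter recovery.

Condition semantics mirror a silencing/depolarization design with cohesin
depletion: inducible loops gain enrichment only in stimulated conditions
(and are robust to depletion); constitutive CTCF loops lose enrichment in
depleted conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals_io import DEStatus, Enhancer, GeneRecord, GenomicInterval, Loop, Peak
from .matrix import ContactMatrix, Primer, PrimerDesign

__all__ = [
    "PlantedLoop",
    "constitutive_ctcf_loop",
    "inducible_ep_loop",
    "SimConfig",
    "ClassSpec",
    "GeneLoopFixtureConfig",
    "simulate_fragments",
    "design_primers",
    "simulate_counts",
    "simulate_gene_loop_fixture",
    "default_sim_config",
    "default_fixture_config",
]

# orientation cycle of the double-alternating design along the region
_ORIENTATION_CYCLE = ("FOR", "LREV", "REV", "LFOR")


@dataclass(frozen=True)
class PlantedLoop:
    """A planted enrichment at one bin pair, with per-condition folds."""

    bin_i: int
    bin_j: int
    fold_by_condition: Mapping[str, float]
    kind: str = "constitutive_ctcf"  # or "inducible_ep"

    def fold(self, condition: str) -> float:
        return float(self.fold_by_condition.get(condition, 1.0))


def constitutive_ctcf_loop(bin_i: int, bin_j: int, fold: float,
                           conditions: Sequence[str]) -> PlantedLoop:
    """CTCF-anchored loop: enriched in every condition except depleted ones."""
    folds = {c: (1.0 if "depleted" in c else fold) for c in conditions}
    return PlantedLoop(bin_i, bin_j, folds, kind="constitutive_ctcf")


def inducible_ep_loop(bin_i: int, bin_j: int, fold: float,
                      conditions: Sequence[str]) -> PlantedLoop:
    """Enhancer-promoter loop: enriched only under stimulation, robust to
    cohesin depletion."""
    folds = {c: (fold if c.startswith("KCl") else 1.0) for c in conditions}
    return PlantedLoop(bin_i, bin_j, folds, kind="inducible_ep")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic 5C experiment.

    Defaults emulate the silencing (TTX) / depolarization (KCl) design
    with two replicates per condition and a cohesin-depletion arm. Region
    and library sizes are desk-scale stand-ins for a Mb-scale 5C region
    sequenced to tens of millions of reads.
    """

    region_length: int = 1_200_000
    mean_fragment_length: int = 3_000
    bin_size: int = 4_000
    decay_exponent: float = 1.0
    library_size: int = 1_000_000
    bias_sd: float = 0.4
    dispersion: float = 0.1
    planted_loops: list[PlantedLoop] = field(default_factory=list)
    loop_anchor_bins: int = 3  # planted anchors span this many bins (12 kb at
    # the default bin size, a realistic anchor width) so that every anchor
    # covers >= 3 fragments and therefore both primer senses
    spike_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    n_replicates: int = 2
    conditions: tuple[str, ...] = ("TTX", "KCl", "TTX_depleted", "KCl_depleted")
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length < 10 * self.bin_size:
            raise ValueError("region_length must be at least 10 bins")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        n_bins = self.region_length // self.bin_size
        for lp in self.planted_loops:
            if not (0 <= lp.bin_i and 0 <= lp.bin_j
                    and lp.bin_i + self.loop_anchor_bins <= n_bins
                    and lp.bin_j + self.loop_anchor_bins <= n_bins):
                raise ValueError(f"planted loop ({lp.bin_i}, {lp.bin_j}) outside region")
            if any(f < 1.0 for f in lp.fold_by_condition.values()):
                raise ValueError("loop enrichment folds must be >= 1")


def default_sim_config(seed: int = 0) -> SimConfig:
    """The packaged study-condition configuration: one constitutive CTCF
    loop and one inducible enhancer-promoter loop planted at distal pixels,
    plus two PCR spike pairs."""
    cfg = SimConfig(seed=seed)
    conditions = cfg.conditions
    n_bins = cfg.region_length // cfg.bin_size
    cfg.planted_loops = [
        constitutive_ctcf_loop(n_bins // 5, 4 * n_bins // 5, 5.0, conditions),
        inducible_ep_loop(n_bins // 3, 2 * n_bins // 3, 5.0, conditions),
    ]
    cfg.spike_pairs = [(10, 120, 50.0), (40, 200, 30.0)]
    return cfg


def simulate_fragments(config: SimConfig) -> list[GenomicInterval]:
    """Tile [0, region_length) with geometric-like random fragment lengths.

    Lengths are min_len + Geometric(p) with mean ``mean_fragment_length``;
    the final fragment is truncated at the region end (merged into its
    neighbour if tiny). Deterministic under the config seed.
    """
    if config.mean_fragment_length < 500:
        raise ValueError("mean_fragment_length must be >= 500 bp")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5f]))
    min_len = 500
    p = 1.0 / max(config.mean_fragment_length - min_len, 1)
    edges = [0]
    while edges[-1] < config.region_length:
        length = min_len + int(rng.geometric(p))
        edges.append(min(edges[-1] + length, config.region_length))
    if len(edges) >= 3 and edges[-1] - edges[-2] < min_len:
        del edges[-2]  # merge a tiny terminal sliver into its neighbour
    if len(edges) - 1 < 4:
        raise ValueError("region too short for at least 4 fragments")
    return [GenomicInterval(config.chrom, a, b) for a, b in zip(edges, edges[1:])]


def design_primers(fragments: Sequence[GenomicInterval]) -> PrimerDesign:
    """One primer per fragment, orientations cycling FOR, LREV, REV, LFOR.

    Forward-sense primers (FOR/LFOR) alternate with reverse-sense primers
    (REV/LREV) along the region so that adjacent fragments always form a
    queryable (opposite-sense) pair, as in the double-alternating scheme.
    """
    if len(fragments) < 4:
        raise ValueError("need at least 4 fragments")
    primers = []
    for i, frag in enumerate(fragments):
        ori = _ORIENTATION_CYCLE[i % 4]
        end = min(frag.start + 30, frag.end)
        primers.append(Primer(f"P{i:04d}_{ori}", i, ori,
                              GenomicInterval(frag.chrom, frag.start, end)))
    return PrimerDesign(primers, list(fragments))


def _loop_enrichment(config: SimConfig, design: PrimerDesign,
                     condition: str) -> np.ndarray:
    """Per-primer-pair enrichment factor from the planted loops.

    A primer belongs to an anchor when its fragment overlaps the anchor
    interval [bin * bin_size, (bin + loop_anchor_bins) * bin_size).
    """
    frag_start = np.array([f.start for f in design.fragments])
    frag_end = np.array([f.end for f in design.fragments])
    frag_of = [p.fragment_index for p in design.primers]
    n = design.n_primers
    L = np.ones((n, n))
    bs = config.bin_size
    wb = config.loop_anchor_bins
    for lp in config.planted_loops:
        fold = lp.fold(condition)
        if fold == 1.0:
            continue
        hits = []
        for b in (lp.bin_i, lp.bin_j):
            lo, hi = b * bs, (b + wb) * bs
            frag_in = (frag_start < hi) & (lo < frag_end)
            hits.append(frag_in[frag_of])
        in_i, in_j = hits
        hit = np.outer(in_i, in_j) | np.outer(in_j, in_i)
        L[hit] *= fold
    return L


def simulate_counts(config: SimConfig, design: PrimerDesign
                    ) -> dict[tuple[str, int], ContactMatrix]:
    """Negative-binomial primer-level count matrices per (condition, rep).

    Expected count at queryable pair (i, j):
        mu_ij = library_size * Z^-1 * d_ij^-alpha * b_i * b_j * L_ij(cond)
    with d_ij the fragment-midpoint distance floored at one bin, b the
    shared log-normal primer biases, L the planted-loop enrichment, and Z
    normalizing the expected total to the library size. Spike pairs are
    multiplied in after counting. Deterministic under the config seed.
    """
    root = np.random.SeedSequence([config.seed, 0xC0])
    bias_ss, counts_ss = root.spawn(2)
    n = design.n_primers
    bias_rng = np.random.default_rng(bias_ss)
    b = bias_rng.lognormal(mean=0.0, sigma=config.bias_sd, size=n)

    mids = np.array([(f.start + f.end) // 2
                     for f in design.fragments])[[p.fragment_index
                                                  for p in design.primers]]
    d = np.abs(np.subtract.outer(mids, mids)).astype(float)
    d = np.maximum(d, config.bin_size)
    queryable = design.queryable_mask()
    decay = d ** (-config.decay_exponent)
    base = decay * np.outer(b, b)

    iu, ju = np.triu_indices(n, k=1)
    q_up = queryable[iu, ju]
    out: dict[tuple[str, int], ContactMatrix] = {}
    rep_streams = counts_ss.spawn(len(config.conditions) * config.n_replicates)
    k = 0
    for condition in config.conditions:
        L = _loop_enrichment(config, design, condition)
        weights = base * L
        z = weights[iu, ju][q_up].sum()
        mu_up = config.library_size * weights[iu, ju] / z
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(rep_streams[k])
            k += 1
            counts_up = np.zeros(iu.size)
            mu_q = mu_up[q_up]
            if config.dispersion > 0:
                r = 1.0 / config.dispersion
                counts_q = rng.negative_binomial(r, r / (r + mu_q))
            else:
                counts_q = rng.poisson(mu_q)
            counts_up[q_up] = counts_q
            counts = np.zeros((n, n))
            counts[iu, ju] = counts_up
            counts[ju, iu] = counts_up
            for (si, sj, fold) in config.spike_pairs:
                if si < n and sj < n and queryable[si, sj]:
                    counts[si, sj] = counts[sj, si] = np.round(counts[si, sj] * fold)
            out[(condition, rep)] = ContactMatrix(
                counts, queryable, design.primer_axis(), level="primer")
    return out


@dataclass(frozen=True)
class ClassSpec:
    """Per-class fixture parameters: loop spans and DE effects."""

    n_genes: int
    span_median: float  # bp, log-normal median of planted loop spans
    span_sigma: float = 0.5  # log-scale sd
    downregulated: bool = False  # adj_p < alpha with negative log2FC in
    # both genotype contrasts when True
    induced: bool = False  # adj_p < alpha and log2FC >= 1 in the
    # induction contrasts when True


@dataclass
class GeneLoopFixtureConfig:
    """Design of the gene/loop/peak/enhancer/DE parameter-recovery fixture.

    Class sizes default to the group sizes of the loop-span comparison
    (18 IEGs, 22 downregulated LRGs, 43 non-deregulated LRGs) plus a
    constitutive background. Downregulated classes carry longer planted
    spans by default, the relationship the downstream statistics recover.
    """

    ieg: ClassSpec = field(default_factory=lambda: ClassSpec(
        18, span_median=120_000, induced=True))
    down_lrg: ClassSpec = field(default_factory=lambda: ClassSpec(
        22, span_median=500_000, downregulated=True, induced=True))
    nondereg_lrg: ClassSpec = field(default_factory=lambda: ClassSpec(
        43, span_median=100_000, induced=True))
    constitutive: ClassSpec = field(default_factory=lambda: ClassSpec(
        60, span_median=150_000))
    genotype_contrasts: tuple[str, str] = ("geno_TTX", "geno_KCl6h")
    induction_contrasts: tuple[str, str] = ("ind_KCl1h_vs_TTX", "ind_KCl6h_vs_TTX")
    alpha: float = 0.05
    max_loops_per_gene: int = 3
    ctcf_anchor_fraction: float = 0.6
    enhancer_loop_fraction: float = 0.6
    anchor_width: int = 10_000
    gene_spacing: int = 4_000_000
    chrom: str = "chrS"
    seed: int = 0


def default_fixture_config(seed: int = 0) -> GeneLoopFixtureConfig:
    return GeneLoopFixtureConfig(seed=seed)


def _de_status(rng: np.random.Generator, spec: ClassSpec, contrast_kind: str,
               alpha: float) -> DEStatus:
    """Draw one DE row consistent with the class's planted rules."""
    if contrast_kind == "genotype":
        if spec.downregulated:
            return DEStatus(log2fc=-float(rng.uniform(0.5, 3.0)),
                            adj_p=float(rng.uniform(1e-6, alpha * 0.8)),
                            expressed=True)
        return DEStatus(log2fc=float(rng.normal(0.0, 0.2)),
                        adj_p=float(rng.uniform(alpha * 2, 0.95)),
                        expressed=True)
    # induction contrast
    if spec.induced:
        return DEStatus(log2fc=float(rng.uniform(1.0, 4.0)),
                        adj_p=float(rng.uniform(1e-6, alpha * 0.8)),
                        expressed=True)
    return DEStatus(log2fc=float(rng.normal(0.0, 0.2)),
                    adj_p=float(rng.uniform(alpha * 2, 0.95)),
                    expressed=True)


def simulate_gene_loop_fixture(config: GeneLoopFixtureConfig
                               ) -> tuple[list[GeneRecord], list[Loop],
                                          list[Peak], list[Enhancer]]:
    """Emit genes, TSS-anchored loops, CTCF peaks, enhancers and DE rows.

    Each gene receives a TSS, 1..max_loops_per_gene loops whose proximal
    anchor contains the TSS and whose midpoint-to-midpoint span is drawn
    from the gene class's log-normal; CTCF peaks land in a configurable
    fraction of anchors and enhancers in the distal anchors of a
    configurable fraction of loops (activity-induced for ARG classes).
    DE rows are drawn to satisfy the class rules by construction, so the
    expression-class assignment round-trips on this fixture.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF1]))
    classes = [
        ("IEG", "IEG", config.ieg, True),
        ("LRG", "down_lrg", config.down_lrg, True),
        ("LRG", "nondereg_lrg", config.nondereg_lrg, True),
        ("constitutive", "constitutive", config.constitutive, False),
    ]
    contrasts = list(config.genotype_contrasts) + list(config.induction_contrasts)
    genes: list[GeneRecord] = []
    loops: list[Loop] = []
    peaks: list[Peak] = []
    enhancers: list[Enhancer] = []
    gene_pos = config.gene_spacing
    half_anchor = config.anchor_width // 2
    for curated_label, class_key, spec, is_arg in classes:
        for g in range(spec.n_genes):
            gene_id = f"{class_key}_{g:03d}"
            tss = GenomicInterval(config.chrom, gene_pos, gene_pos + 1)
            de = {}
            for c in config.genotype_contrasts:
                de[c] = _de_status(rng, spec, "genotype", config.alpha)
            for c in config.induction_contrasts:
                de[c] = _de_status(rng, spec, "induction", config.alpha)
            genes.append(GeneRecord(gene_id, tss, curated_label, de))

            n_loops = int(rng.integers(1, config.max_loops_per_gene + 1))
            for _ in range(n_loops):
                span = spec.span_median * math.exp(
                    spec.span_sigma * rng.standard_normal())
                span = max(span, 2.5 * config.anchor_width)
                proximal = GenomicInterval(config.chrom,
                                           gene_pos - half_anchor,
                                           gene_pos + half_anchor)
                distal_mid = gene_pos + int(round(span))
                distal = GenomicInterval(config.chrom,
                                         distal_mid - half_anchor,
                                         distal_mid + half_anchor)
                loops.append(Loop(proximal, distal))
                for anchor in (proximal, distal):
                    if rng.random() < config.ctcf_anchor_fraction:
                        mid = (anchor.start + anchor.end) // 2
                        peaks.append(Peak(GenomicInterval(config.chrom,
                                                          mid - 250, mid + 250),
                                          "CTCF"))
                if rng.random() < config.enhancer_loop_fraction:
                    mid = (distal.start + distal.end) // 2
                    enhancers.append(Enhancer(
                        GenomicInterval(config.chrom, mid - 500, mid + 500),
                        inducible=is_arg or bool(rng.random() < 0.5)))
            gene_pos += config.gene_spacing
    return genes, loops, peaks, enhancers
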