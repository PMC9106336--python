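# loopscore

Chromatin-contact analysis for targeted 5C experiments, plus the
loop-span genomics that links contact structure to gene regulation.

Neuronal genes that depend on cohesin for full expression tend to form
long chromatin loops, while short-loop genes (for example immediate early
genes) stay inducible after cohesin loss. Testing that relationship needs
two analysis layers, both implemented here:

1. **5C interaction scoring** — from raw primer-pair read counts to
   Background-corrected Interaction Scores. Read pairs are tallied when one
   end maps to a forward/left-forward primer and the other to a
   reverse/left-reverse primer (the double-alternating design); PCR-bias
   outliers are removed where a count is ≥ 8× the median of the 5×5
   window around it; primer counts are averaged into fragment–fragment
   counts, summed into 4 kb bins through 12 kb windows, ICE-balanced per
   replicate, and quantile-normalized across replicates. The expected
   signal at each pixel comes from the donut background model (a ring of
   surrounding pixels rescaled by the distance-decay reference), and the
   observed/expected ratios are fit with a logistic distribution whose
   upper-tail p-values become scores:

   `score(i, j) = -10 · log2(p)` so p = 0.5 → 10, p = 0.25 → 20.

2. **Loop-span genomics** — loops (BEDPE anchors) are classified as CTCF
   loops (a CTCF peak in either anchor) or enhancer–promoter loops (a TSS
   in one anchor, an enhancer in the other); loop span is the distance
   between anchor midpoints; genes are assigned expression classes
   (IEG, downregulated LRG, non-deregulated LRG, constitutive, inducible)
   from differential-expression tables under explicit adjusted-p and
   fold-change rules; and span distributions are compared between classes
   with two-sample Kolmogorov–Smirnov tests, with Fisher exact tests for
   promoter peak-binding enrichment.

A synthetic-data module generates every input with planted, recoverable
structure: multi-replicate, multi-condition 5C counts with power-law
distance decay, log-normal primer biases, negative-binomial noise,
planted constitutive-CTCF and inducible enhancer–promoter loops, and PCR
spike pairs; and gene/loop/peak/enhancer/DE fixtures in which
downregulated gene classes carry longer planted loop spans.

## Worked example

Run both analyses end to end on the packaged synthetic design
(four conditions — TTX, KCl, and their cohesin-depleted counterparts —
two replicates each, one constitutive CTCF loop and one inducible
enhancer–promoter loop planted at 5-fold enrichment):

```sh
loopscore run-all --seed 1 --outdir out/
```

`out/fivec/loop_quantification.tsv` then contains, per planted loop and
condition, the mean interaction frequency, the distance-corrected loop
strength (mean observed/expected over the anchor rectangle) and the mean
interaction score. With seed 1:

```
             kind    condition  distance_corrected_strength  mean_interaction_score
constitutive_ctcf          TTX                     2.723435              201.750446
constitutive_ctcf          KCl                     2.956878              219.513595
constitutive_ctcf TTX_depleted                     1.078925               19.014924
constitutive_ctcf KCl_depleted                     0.871591                6.044983
     inducible_ep          TTX                     1.076687               17.897128
     inducible_ep          KCl                     2.711229              203.276245
     inducible_ep TTX_depleted                     0.924570               13.639958
     inducible_ep KCl_depleted                     2.484910              175.094553
```

The constitutive CTCF loop is strong in both control conditions
(strength ≈ 2.7–3.0) and collapses to background (≈ 1.0) under
simulated cohesin depletion; the inducible enhancer–promoter loop
appears only under KCl stimulation (2.7 vs 1.1 at baseline) and is
robust to depletion — the planted condition structure, recovered by the
scoring pipeline.

`out/loopspan/ks_statistics.tsv` holds the span comparisons. With the
default fixture (22 downregulated vs 43 non-deregulated late-response
genes, planted longest-span medians 500 kb vs 100 kb), the longest-span
KS test gives D = 0.95, p ≈ 1.5e-20 — the planted span–dysregulation
relationship.

Library use without the CLI:

```python
from loopscore.synthetic import default_sim_config, simulate_fragments, \
    design_primers, simulate_counts
from loopscore.matrix import remove_outliers, primer_to_fragment, bin_to_grid
from loopscore.normalization import ice_balance, quantile_normalize
from loopscore.scoring import donut_expected, background_normalize, \
    fit_logistic, pvalues_and_scores

cfg = default_sim_config(seed=1)
design = design_primers(simulate_fragments(cfg))
counts = simulate_counts(cfg, design)   # {(condition, replicate): matrix}
```

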