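"""Configuration-driven orchestration of the two analyses.

``run_5c_pipeline`` executes the contact pipeline end to end on synthetic
reads — tally, outlier removal, fragment conversion, binning, ICE,
quantile normalization, donut scoring, loop quantification — and
``run_loopspan_analysis`` runs the loop-span/expression-class statistics
on the synthetic gene-loop fixture. Both are deterministic under the
config seed, write plain TSV/JSON artifacts, and record a manifest with
parameter values, per-stage counts and output checksums. Every output
table carries the run hash in a leading comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import genomics, normalization, scoring
from .intervals_io import GenomicInterval
from .matrix import ContactMatrix, PrimerDesign, bin_to_grid, primer_to_fragment, \
    remove_outliers, tally_pair_counts
from .synthetic import GeneLoopFixtureConfig, SimConfig, default_fixture_config, \
    default_sim_config, design_primers, simulate_counts, simulate_fragments, \
    simulate_gene_loop_fixture

logger = logging.getLogger(__name__)

__all__ = ["FivecParams", "LoopspanParams", "PipelineConfig",
           "run_5c_pipeline", "run_loopspan_analysis"]


@dataclass
class FivecParams:
    outlier_fold: float = 8.0
    bin_size: int = 4_000
    window: int = 12_000
    ice_tol: float = 1e-8
    ice_max_iter: int = 500
    min_separation: int = 1
    donut_width: int = 5
    donut_exclusion: int = 2
    min_ring_pixels: int = 10
    p_floor: float = 1e-12

    def validate(self) -> None:
        if self.window < self.bin_size:
            raise ValueError("window must be >= bin_size")
        if self.outlier_fold <= 1:
            raise ValueError("outlier_fold must exceed 1")
        if self.donut_width <= self.donut_exclusion:
            raise ValueError("donut_width must exceed donut_exclusion")


@dataclass
class LoopspanParams:
    alpha: float = 0.05
    induction_lfc: float = 1.0
    promoter_halfwidth: int = 2_000


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=default_sim_config)
    fixture: GeneLoopFixtureConfig = field(default_factory=default_fixture_config)
    fivec: FivecParams = field(default_factory=FivecParams)
    loopspan: LoopspanParams = field(default_factory=LoopspanParams)

    def __post_init__(self) -> None:
        # one pipeline seed governs both generators
        self.sim.seed = self.seed
        self.fixture.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        cfg = cls(seed=int(raw.get("seed", 0)))
        for section, target in (("sim", cfg.sim), ("fixture", cfg.fixture),
                                ("fivec", cfg.fivec), ("loopspan", cfg.loopspan)):
            for key, value in (raw.get(section) or {}).items():
                if not hasattr(target, key):
                    raise ValueError(f"unknown {section} parameter {key!r}")
                setattr(target, key, value)
        cfg.sim.seed = cfg.seed
        cfg.fixture.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict[str, Any]:
        def clean(obj: Any) -> Any:
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return clean({
            "seed": self.seed,
            "sim": asdict(self.sim),
            "fixture": asdict(self.fixture),
            "fivec": asdict(self.fivec),
            "loopspan": asdict(self.loopspan),
        })


def _run_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, run_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# run: {run_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _matrix_to_triplets(matrix: ContactMatrix) -> pd.DataFrame:
    iu, ju = np.triu_indices(matrix.n)
    keep = matrix.informative[iu, ju]
    return pd.DataFrame({"bin_i": iu[keep], "bin_j": ju[keep],
                         "value": matrix.values[iu[keep], ju[keep]]})


def _expand_to_assignments(matrix: ContactMatrix,
                           design: PrimerDesign) -> list[tuple[str, str]]:
    """Replay a simulated count matrix as per-read primer-pair assignments."""
    ids = [p.primer_id for p in design.primers]
    iu, ju = np.triu_indices(matrix.n, k=1)
    counts = matrix.values[iu, ju].astype(int)
    keep = counts > 0
    reps_i = np.repeat(iu[keep], counts[keep])
    reps_j = np.repeat(ju[keep], counts[keep])
    return [(ids[i], ids[j]) for i, j in zip(reps_i, reps_j)]


def run_5c_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full contact pipeline on synthetic reads; return the manifest."""
    config.fivec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_hash = _run_hash(config)
    fp = config.fivec
    stages: list[dict[str, Any]] = []

    fragments = simulate_fragments(config.sim)
    design = design_primers(fragments)
    simulated = simulate_counts(config.sim, design)
    stages.append({"stage": "simulate", "fragments": len(fragments),
                   "primers": design.n_primers, "replicates": len(simulated)})

    region = GenomicInterval(config.sim.chrom, 0, config.sim.region_length)
    tallied: dict[tuple[str, int], ContactMatrix] = {}
    n_tallied = n_discarded = 0
    for key, mat in simulated.items():
        res = tally_pair_counts(_expand_to_assignments(mat, design), design)
        tallied[key] = res.matrix
        n_tallied += res.n_tallied
        n_discarded += res.n_discarded
    stages.append({"stage": "tally", "pairs_tallied": n_tallied,
                   "pairs_discarded": n_discarded})

    filtered: dict[tuple[str, int], ContactMatrix] = {}
    n_removed = 0
    for key, mat in tallied.items():
        out, removed = remove_outliers(mat, fold=fp.outlier_fold)
        filtered[key] = out
        n_removed += len(removed)
    stages.append({"stage": "outlier_removal", "pairs_removed": n_removed})

    frag_mats = {key: primer_to_fragment(mat, design)
                 for key, mat in filtered.items()}
    stages.append({"stage": "fragment_conversion",
                   "fragments": len(design.fragments)})

    binned = {key: bin_to_grid(mat, fp.bin_size, fp.window, region)
              for key, mat in frag_mats.items()}
    n_bins = next(iter(binned.values())).n
    stages.append({"stage": "binning", "bins": n_bins})

    balanced = {}
    for key, mat in binned.items():
        bal = normalization.ice_balance(mat, tol=fp.ice_tol,
                                        max_iter=fp.ice_max_iter,
                                        min_separation=fp.min_separation)
        balanced[key] = bal
        logger.info("ICE %s: %d iterations, converged=%s", key,
                    bal.n_iterations, bal.converged)
    stages.append({"stage": "ice", "converged": sum(b.converged for b in
                                                    balanced.values())})

    keys = list(balanced)
    observed = dict(zip(keys, normalization.quantile_normalize(
        [balanced[k].matrix for k in keys])))
    stages.append({"stage": "quantile_normalization", "matrices": len(keys)})

    score_rows = []
    expected_maps: dict[tuple[str, int], scoring.ExpectedMatrix] = {}
    score_maps: dict[tuple[str, int], scoring.ScoreMap] = {}
    for key, mat in observed.items():
        expected = scoring.donut_expected(mat, fp.donut_width,
                                          fp.donut_exclusion, fp.min_ring_pixels)
        ratio = scoring.background_normalize(mat, expected)
        finite = ratio[~np.isnan(ratio)]
        mu, s = scoring.fit_logistic(finite)
        smap = scoring.pvalues_and_scores(ratio, mu, s, fp.p_floor)
        expected_maps[key] = expected
        score_maps[key] = smap
        score_rows.append({"condition": key[0], "replicate": key[1],
                           "pixels_scored": int(finite.size),
                           "logistic_location": mu, "logistic_scale": s})
    stages.append({"stage": "scoring",
                   "pixels_scored": int(sum(r["pixels_scored"]
                                            for r in score_rows))})

    # condition-level loop quantification at the planted anchor bins
    loop_rows = []
    bs = config.sim.bin_size
    wb = config.sim.loop_anchor_bins
    for li, lp in enumerate(config.sim.planted_loops):
        anchor_a = GenomicInterval(config.sim.chrom, lp.bin_i * bs, (lp.bin_i + wb) * bs)
        anchor_b = GenomicInterval(config.sim.chrom, lp.bin_j * bs, (lp.bin_j + wb) * bs)
        for condition in config.sim.conditions:
            reps = [k for k in keys if k[0] == condition]
            freqs, strengths, scores = [], [], []
            for k in reps:
                q = scoring.quantify_loop_pixels(observed[k], anchor_a, anchor_b)
                dc = scoring.distance_corrected_loop_strength(
                    observed[k], expected_maps[k], anchor_a, anchor_b)
                freqs.append(q.mean)
                strengths.append(dc.mean)
                rows = scoring._anchor_bins(observed[k], anchor_a)
                cols = scoring._anchor_bins(observed[k], anchor_b)
                block = score_maps[k].score[np.ix_(rows, cols)]
                scores.append(float(np.nanmean(block)))
            loop_rows.append({
                "loop": li, "kind": lp.kind, "condition": condition,
                "bin_i": lp.bin_i, "bin_j": lp.bin_j,
                "mean_interaction_frequency": float(np.nanmean(freqs)),
                "distance_corrected_strength": float(np.nanmean(strengths)),
                "mean_interaction_score": float(np.nanmean(scores)),
            })
    stages.append({"stage": "loop_quantification", "rows": len(loop_rows)})

    axis = next(iter(observed.values())).axis
    _write_table(axis, outdir / "bins.tsv", run_hash)
    for key in keys:
        name = f"{key[0]}_rep{key[1]}"
        _write_table(_matrix_to_triplets(observed[key]),
                     outdir / f"observed_{name}.tsv", run_hash)
        smap = score_maps[key]
        iu, ju = np.triu_indices(observed[key].n)
        defined = ~np.isnan(smap.ratio[iu, ju])
        _write_table(pd.DataFrame({
            "bin_i": iu[defined], "bin_j": ju[defined],
            "obs": observed[key].values[iu[defined], ju[defined]],
            "exp": expected_maps[key].values[iu[defined], ju[defined]],
            "ratio": smap.ratio[iu[defined], ju[defined]],
            "p": smap.p_value[iu[defined], ju[defined]],
            "score": smap.score[iu[defined], ju[defined]],
        }), outdir / f"scores_{name}.tsv", run_hash)
    _write_table(pd.DataFrame(score_rows), outdir / "logistic_fits.tsv", run_hash)
    _write_table(pd.DataFrame(loop_rows), outdir / "loop_quantification.tsv",
                 run_hash)

    outputs = sorted(p.name for p in outdir.glob("*.tsv"))
    manifest = {
        "run_hash": run_hash,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": stages,
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


_CLASS_PAIRS = [("downregulated_LRG", "non_deregulated_LRG"),
                ("IEG", "downregulated_LRG"),
                ("IEG", "non_deregulated_LRG")]


def run_loopspan_analysis(config: PipelineConfig,
                          outdir: str | Path) -> dict[str, Any]:
    """Run the loop-span/expression statistics on the synthetic fixture."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_hash = _run_hash(config)
    lp = config.loopspan
    fixture = config.fixture
    stages: list[dict[str, Any]] = []

    genes, loops, peaks, enhancers = simulate_gene_loop_fixture(fixture)
    stages.append({"stage": "fixture", "genes": len(genes), "loops": len(loops),
                   "ctcf_peaks": len(peaks), "enhancers": len(enhancers)})

    classified = genomics.classify_loops(loops, peaks, genes, enhancers)
    stages.append({"stage": "classification", "records": len(classified),
                   "ctcf_loops": sum(c.is_ctcf for c in classified),
                   "ep_loops": sum(c.is_enhancer_promoter for c in classified)})

    contrasts = genomics.ExpressionContrasts(
        genotype=fixture.genotype_contrasts,
        induction=fixture.induction_contrasts)
    ieg_ids = [g.gene_id for g in genes if g.class_label == "IEG"]
    lrg_ids = [g.gene_id for g in genes if g.class_label == "LRG"]
    assignments = genomics.assign_expression_classes(
        genes, contrasts, ieg_ids, lrg_ids, lp.alpha, lp.induction_lfc)
    assign_df = pd.DataFrame([asdict(a) for a in assignments])
    stages.append({"stage": "expression_classes",
                   "classes": {str(k): int(v) for k, v in
                               assign_df["expression_class"]
                               .value_counts().items()}})

    class_of = dict(zip(assign_df["gene_id"], assign_df["expression_class"]))
    stat_rows = []
    span_tables = {}
    for loop_filter in ("all", "ctcf", "enhancer_promoter"):
        for statistic in ("longest", "mean"):
            table = genomics.span_table(genes, classified, loop_filter, statistic)
            table["expression_class"] = table["gene_id"].map(class_of)
            span_tables[(loop_filter, statistic)] = table
            usable = table[table["included"]]
            for cls_a, cls_b in _CLASS_PAIRS:
                a = usable.loc[usable["expression_class"] == cls_a, "span"]
                b = usable.loc[usable["expression_class"] == cls_b, "span"]
                row = {"filter": loop_filter, "statistic": statistic,
                       "class_a": cls_a, "class_b": cls_b,
                       "n_a": len(a), "n_b": len(b)}
                if len(a) and len(b):
                    ks = genomics.ks_two_sample(a.to_numpy(), b.to_numpy())
                    row.update(D=ks.statistic, p=ks.pvalue, computable=True)
                else:
                    row.update(D=float("nan"), p=float("nan"), computable=False)
                stat_rows.append(row)
    stages.append({"stage": "ks_statistics", "rows": len(stat_rows)})

    arg_ids = set(ieg_ids) | set(lrg_ids)
    interest = [g for g in genes if g.gene_id in arg_ids]
    background = [g for g in genes if g.gene_id not in arg_ids]
    enr_rows = []
    if interest and background:
        enr = genomics.promoter_binding_enrichment(
            interest, background, peaks, lp.promoter_halfwidth)
        enr_rows.append({"peak_set": "CTCF", "interest": "ARG",
                         "background": "non-ARG",
                         "bound_interest": enr.table[0][0],
                         "unbound_interest": enr.table[0][1],
                         "bound_background": enr.table[1][0],
                         "unbound_background": enr.table[1][1],
                         "odds_ratio": enr.odds_ratio, "p": enr.pvalue})
    stages.append({"stage": "promoter_enrichment", "rows": len(enr_rows)})

    loop_df = pd.DataFrame([{
        "chrom": c.loop.anchor1.chrom,
        "start1": c.loop.anchor1.start, "end1": c.loop.anchor1.end,
        "start2": c.loop.anchor2.start, "end2": c.loop.anchor2.end,
        "span": c.span, "is_ctcf": c.is_ctcf,
        "is_enhancer_promoter": c.is_enhancer_promoter,
        "gene_id": c.gene_id if c.gene_id else "",
    } for c in classified])
    _write_table(loop_df, outdir / "classified_loops.tsv", run_hash)
    _write_table(assign_df, outdir / "class_assignments.tsv", run_hash)
    for (loop_filter, statistic), table in span_tables.items():
        _write_table(table, outdir / f"spans_{loop_filter}_{statistic}.tsv",
                     run_hash)
    _write_table(pd.DataFrame(stat_rows), outdir / "ks_statistics.tsv", run_hash)
    _write_table(pd.DataFrame(enr_rows), outdir / "promoter_enrichment.tsv",
                 run_hash)

    outputs = sorted(p.name for p in outdir.glob("*.tsv"))
    manifest = {
        "run_hash": run_hash,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": stages,
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
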