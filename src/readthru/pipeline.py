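"""End-to-end orchestration: simulate (or load) -> classify -> metagene
indices -> DoG calling and controls -> replication-timing geometry ->
summary report.

Every stage is a pure function of (inputs, config); the pipeline only
sequences them and writes artifacts. Rerunning with the same seed
reproduces the summary byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, dogs, metagene, pausing, replication
from .io import bin_coverage, write_bedgraph, write_intervals
from .model import CoverageTrack, GeneModel, ReadRecord
from .simulate import SimulationConfig, simulate_genome, simulate_reads, simulate_repliseq, write_annotation_gtf, write_truth

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    conditions: list[str] | None = None     # default: all conditions in the simulation
    control_condition: str = "DMSO"
    dog_condition: str = "SN38+JQ1"
    min_expression_fpkm: float = 1.0
    profile_bin_size: int = 500
    body_bins: int = 100
    flank: int = 5_000
    min_dog_length: int = 12_000
    dog_window: int = 2_000
    dog_coverage_threshold: float = 0.1
    hs_cpm: float = 1.5
    hs_range: tuple[int, int] = (30_000, 45_000)
    repli_epsilon: float = 0.5
    repli_smoothing_bp: int = 50_000
    min_segment_length: int = 100_000
    exclude_chroms: list[str] = field(default_factory=list)
    fc_window: int = 250
    min_tc: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = d.get("simulation", {})
        bad = set(sim) - _SIM_FIELDS
        if bad:
            raise ValueError(f"unknown simulation keys: {sorted(bad)}")
        cfg = cls(**d)
        if isinstance(cfg.hs_range, list):
            cfg.hs_range = tuple(cfg.hs_range)
        return cfg

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def stranded_tracks(
    reads: list[ReadRecord], bin_size: int, chrom_sizes: dict[str, int]
) -> dict[str, CoverageTrack]:
    """Per-strand coverage sharing one library size (total target reads),
    so CPM is comparable across strands."""
    target = [r for r in reads if r.genome == "target"]
    lib = len(target)
    out = {}
    for strand in ("+", "-"):
        sub = [r for r in target if r.strand == strand]
        t = bin_coverage(sub, bin_size, chrom_sizes)
        out[strand] = CoverageTrack(bin_size, t.counts, library_size=lib)
    return out


def gene_expression(
    reads: list[ReadRecord], genes: list[GeneModel]
) -> pd.DataFrame:
    """Per-gene read counts (midpoint within the gene span), CPM and FPKM."""
    per_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append(g)
    arrays = {}
    for chrom, gs in per_chrom.items():
        gs.sort(key=lambda g: g.start)
        arrays[chrom] = (np.array([g.start for g in gs]),
                         np.array([g.end for g in gs]), gs)
    counts = {g.gene_id: 0 for g in genes}
    lib = 0
    for r in reads:
        if r.genome != "target":
            continue
        lib += 1
        if r.chrom not in arrays:
            continue
        starts, ends, gs = arrays[r.chrom]
        i = int(np.searchsorted(starts, r.midpoint, side="right")) - 1
        if i >= 0 and r.midpoint < ends[i]:
            counts[gs[i].gene_id] += 1
    df = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "length": [g.length for g in genes],
        "count": [counts[g.gene_id] for g in genes],
    })
    lib = max(lib, 1)
    df["cpm"] = df["count"] * 1e6 / lib
    df["fpkm"] = df["cpm"] / (df["length"] / 1e3)
    return df.set_index("gene_id")


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic-study analysis and return the summary dict.

    Stages: genome simulation; per-condition read simulation, exonic/nascent
    classification and NERD/SLAM indices; DoG calling with high-stringency
    tier, matched controls and next-gene distances on the readthrough
    condition; Repli-seq RT segmentation (on the untreated condition) with
    per-condition region coverage and DoG-vs-control boundary distances;
    length-ordered fold-change curve.
    """
    cfg = config.sim_config()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(_round(dataclasses.asdict(config)), indent=1, sort_keys=True)
        )
    genes, chrom_sizes, truth = simulate_genome(cfg)
    if out is not None:
        write_annotation_gtf(genes, out / "annotation.gtf")
        write_truth(truth, out / "truth.tsv")
    expressed_mask = truth["fpkm"] >= config.min_expression_fpkm
    expressed = [g for g, keep in zip(genes, expressed_mask) if keep]
    longest = metagene.select_longest_decile(genes)
    conditions = config.conditions or list(cfg.conditions)
    summary: dict = {"n_genes": len(genes), "n_expressed": len(expressed),
                     "conditions": {}}
    per_cond_reads: dict[str, list[ReadRecord]] = {}
    spike_counts: dict[str, int] = {}
    expr_tables: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        reads = simulate_reads(genes, truth, cfg, cond)
        per_cond_reads[cond] = reads
        spike_counts[cond] = classify.count_spikein(reads)
        ex = classify.split_exonic(reads, genes)
        na = classify.split_nascent(reads, min_conversions=config.min_tc)
        nonexonic_track = bin_coverage(ex.negative, config.profile_bin_size, chrom_sizes)
        nascent_track = bin_coverage(na.positive, config.profile_bin_size, chrom_sizes)
        nerd = metagene.elongation_index(
            metagene.metagene_profile(nonexonic_track, longest,
                                      n_body_bins=config.body_bins, flank=config.flank),
            variant="NERD")
        slam = metagene.elongation_index(
            metagene.metagene_profile(nascent_track, longest,
                                      n_body_bins=config.body_bins, flank=config.flank),
            variant="SLAM")
        expr_tables[cond] = gene_expression(ex.positive, genes)
        summary["conditions"][cond] = {
            "n_reads": sum(1 for r in reads if r.genome == "target"),
            "n_exonic": len(ex.positive), "n_nonexonic": len(ex.negative),
            "n_nascent": len(na.positive), "spikein": spike_counts[cond],
            "nerd_index": nerd.slope, "slam_index": slam.slope,
        }
    summary["chiprx_scale_factors"] = classify.chiprx_scale_factor(spike_counts)

    # --- DoG calling on the readthrough condition -------------------------
    dc = config.dog_condition
    reads = per_cond_reads[dc]
    ex = classify.split_exonic(reads, genes)
    tracks = stranded_tracks(ex.negative, config.profile_bin_size, chrom_sizes)
    calls = dogs.call_dogs(
        tracks, expressed, min_dog_length=config.min_dog_length,
        window=config.dog_window, coverage_threshold=config.dog_coverage_threshold,
        condition=dc)
    hs = dogs.high_stringency_filter(calls, cpm_threshold=config.hs_cpm,
                                     cpm_range=config.hs_range)
    called = {c.gene_id for c in calls}
    truth_idx = truth.set_index("gene_id")
    true_dogs = set(truth_idx.index[truth_idx["is_dog"] & (
        truth_idx["fpkm"] >= config.min_expression_fpkm)])
    tp = len(called & true_dogs)
    recall = tp / len(true_dogs) if true_dogs else float("nan")
    precision = tp / len(called) if called else float("nan")
    expr_dc = expr_tables[dc]
    dog_df = truth_idx.loc[sorted(called & set(truth_idx.index))].reset_index()
    pool_df = truth_idx.loc[[g.gene_id for g in expressed
                             if g.gene_id not in called]].reset_index()
    controls = dogs.match_controls(
        dog_df[["gene_id", "length", "fpkm"]],
        pool_df[["gene_id", "length", "fpkm"]], seed=config.seed)
    dog_ids = set(dog_df["gene_id"])
    ctrl_ids = set(controls.pairs["control_gene_id"])
    gene_by_id = {g.gene_id: g for g in genes}
    dist_dog = [dogs.distance_to_next_expressed_gene(gene_by_id[g], expressed)
                for g in sorted(dog_ids)]
    dist_ctrl = [dogs.distance_to_next_expressed_gene(gene_by_id[g], expressed)
                 for g in sorted(ctrl_ids)]
    summary["dogs"] = {
        "condition": dc, "n_called": len(calls), "n_high_stringency": len(hs),
        "n_true_dogs_expressed": len(true_dogs),
        "recall": recall, "precision": precision,
        "median_dog_length": float(np.median([c.dog_length for c in calls])) if calls else 0.0,
        "median_matching_distance": float(controls.pairs["distance"].median()) if len(controls.pairs) else 0.0,
        "median_dist_next_gene_dog": float(np.median([d for d in dist_dog if np.isfinite(d)])) if dist_dog else 0.0,
        "median_dist_next_gene_control": float(np.median([d for d in dist_ctrl if np.isfinite(d)])) if dist_ctrl else 0.0,
    }
    if out is not None:
        controls.pairs.to_csv(out / "control_pairs.tsv", sep="\t", index=False)
        pd.DataFrame([{
            "gene_id": c.gene_id, "chrom": c.chrom, "strand": c.strand,
            "tes": c.tes, "dog_length": c.dog_length, "tier": c.tier,
        } for c in calls]).to_csv(out / "dog_calls.tsv", sep="\t", index=False)

    # --- replication timing ----------------------------------------------
    e0, l0 = simulate_repliseq(truth, cfg, config.control_condition)
    rt0 = replication.rt_profile(e0, l0, epsilon=config.repli_epsilon,
                                 smoothing_bp=config.repli_smoothing_bp)
    segments = replication.segment_rt(rt0, min_segment_length=config.min_segment_length)
    repli_summary: dict = {"n_segments": {c: len(s) for c, s in segments.segments.items()}}
    for cond in conditions:
        e, l = simulate_repliseq(truth, cfg, cond)
        late_l = replication.region_coverage(l, segments, "late")["cpm"].sum()
        early_l = replication.region_coverage(l, segments, "early")["cpm"].sum()
        early_e = replication.region_coverage(e, segments, "early")["cpm"].sum()
        repli_summary[cond] = {
            "late_L_cpm_total": float(late_l),
            "early_E_cpm_total": float(early_e),
            # depth-free readout of late-replication rescue
            "late_L_share": float(late_l / (late_l + early_l)),
        }
    keep_genes = replication.exclude_chromosomes(
        [gene_by_id[g] for g in sorted(dog_ids)], config.exclude_chroms)
    keep_ctrl = replication.exclude_chromosomes(
        [gene_by_id[g] for g in sorted(ctrl_ids)], config.exclude_chroms)
    bd_dog = [replication.distance_to_boundary(g, segments) for g in keep_genes]
    bd_ctrl = [replication.distance_to_boundary(g, segments) for g in keep_ctrl]
    bd_dog = [d for d in bd_dog if d is not None]
    bd_ctrl = [d for d in bd_ctrl if d is not None]
    repli_summary["median_boundary_dist_dog"] = float(np.median(bd_dog)) if bd_dog else None
    repli_summary["median_boundary_dist_control"] = float(np.median(bd_ctrl)) if bd_ctrl else None
    dirs = {}
    for c in calls:
        d = replication.readthrough_direction(gene_by_id[c.gene_id], c.dog_length, segments)
        dirs[d] = dirs.get(d, 0) + 1
    repli_summary["readthrough_direction_counts"] = dict(sorted(dirs.items()))
    summary["replication"] = repli_summary

    # --- length-dependent fold change ------------------------------------
    fc = pausing.moving_average_fc(
        expr_tables[dc]["cpm"], expr_tables[config.control_condition]["cpm"],
        expr_tables[dc]["length"], window=config.fc_window)
    n10 = max(1, len(fc) // 10)
    summary["length_fc"] = {
        "n_genes": len(fc),
        "ma_shortest_decile": float(fc["ma_log2_fc"].head(n10).mean()),
        "ma_longest_decile": float(fc["ma_log2_fc"].tail(n10).mean()),
    }
    summary = _round(summary)
    if out is not None:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
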