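"""Shared fixtures: small constructed tracks and session-scoped simulation
metric bundles reused by several test modules (the simulations are the
expensive part, so they run once)."""

from __future__ import annotations

import numpy as np
import pytest

from readthru import (
    CoverageTrack,
    GeneModel,
    SimulationConfig,
    call_dogs,
    elongation_index,
    high_stringency_filter,
    metagene_profile,
    select_longest_decile,
    simulate_genome,
    simulate_reads,
    split_exonic,
    split_nascent,
)
from readthru.io import bin_coverage
from readthru.pipeline import stranded_tracks

GOLDEN_CONFIG = {
    "seed": 42,
    "simulation": {
        "n_genes": 80,
        "n_chroms": 1,
        "chrom_length": 12_000_000,
        "mean_reads_per_gene": 800,
        "spikein_reads": 5_000,
    },
    "fc_window": 20,
}


def uniform_track(value: float = 2.0, n_bins: int = 400, bin_size: int = 50,
                  chrom: str = "chr1", library_size: int = 1_000_000) -> CoverageTrack:
    return CoverageTrack(bin_size, {chrom: np.full(n_bins, value)}, library_size)


def make_gene(gene_id="G1", chrom="chr1", strand="+", start=5_000, end=15_000,
              exons=(), isoform_id=None) -> GeneModel:
    return GeneModel(gene_id=gene_id, isoform_id=isoform_id or f"{gene_id}.1",
                     chrom=chrom, strand=strand, start=start, end=end,
                     exons=tuple(exons))


@pytest.fixture(scope="session")
def simulation_metrics():
    """Run the default-scale study on three seeds and collect the metrics
    the recovery tests need: DoG recall/precision, high-stringency subset
    status, and SLAM/NERD slopes for untreated vs elongation-blocked
    conditions."""
    out = {}
    for seed in (1, 2, 3):
        cfg = SimulationConfig(n_genes=300, seed=seed)
        genes, sizes, truth = simulate_genome(cfg)
        longest = select_longest_decile(genes)
        expressed = [g for g, keep in zip(genes, truth["fpkm"] >= 1.0) if keep]
        res = {"slam": {}, "nerd": {}}
        for cond in ("DMSO", "SN38+JQ1"):
            reads = simulate_reads(genes, truth, cfg, cond)
            ex = split_exonic(reads, genes)
            na = split_nascent(reads)
            for variant, subset in (("slam", na.positive), ("nerd", ex.negative)):
                track = bin_coverage(subset, 500, sizes)
                prof = metagene_profile(track, longest)
                res[variant][cond] = elongation_index(prof, variant.upper()).slope
            if cond == "SN38+JQ1":
                tracks = stranded_tracks(ex.negative, 500, sizes)
                calls = call_dogs(tracks, expressed)
                hs = high_stringency_filter(calls)
                called = {c.gene_id for c in calls}
                ti = truth.set_index("gene_id")
                true_dogs = set(ti.index[ti["is_dog"] & (ti["fpkm"] >= 1.0)])
                tp = len(called & true_dogs)
                res["recall"] = tp / len(true_dogs)
                res["precision"] = tp / len(called)
                res["called"] = called
                res["hs_called"] = {c.gene_id for c in hs}
                res["dog_lengths"] = {c.gene_id: c.dog_length for c in calls}
                res["truth"] = truth
            del reads, ex, na
        out[seed] = res
    return out


@pytest.fixture(scope="session")
def golden_run(tmp_path_factory):
    """One pipeline run of the bundled seed-42 configuration."""
    from readthru.pipeline import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("golden")
    cfg = PipelineConfig.from_dict(GOLDEN_CONFIG)
    with np.errstate(all="ignore"):
        summary = run_pipeline(cfg, outdir)
    return summary, outdir
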