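# readthru

Analysis toolkit for **readthrough (downstream-of-gene, DoG) transcription**
and its genomic consequences, built for studies of transcription-elongation
inhibition — e.g. combined TOP1-poison / BET-inhibitor treatment of tumor
cells, where RNA polymerase II fails to terminate and runs tens to hundreds
of kilobases past the transcription end site (TES), eventually colliding
with the replication program.

The package is aimed at computational genomicists who have aligned
short-read data (SLAM-seq, RNA-seq, ChIP-Rx-seq, Repli-seq) and want a
tested, scriptable implementation of the analysis chain, together with a
ground-truthed synthetic-data generator for validating every stage.

## What it computes

**Elongation indices.** Nascent transcription is profiled along a scaled
gene body (TSS → TES, 100 bins, ±5 kb flanks) and summarized as the slope
of an ordinary least-squares fit of mean CPM on scaled position
*u* ∈ [0, 1]:

- **SLAM index** — slope computed on reads carrying T>C conversions from
  4sU metabolic labeling (direct nascent reads);
- **NERD index** — the same slope on nonexonic (intronic) reads, a
  labeling-free proxy usable in vivo.

A 5′ shift of nascent RNA (elongation block) drives both slopes down.

**DoG calling.** From each expressed gene's TES, coverage is extended in
2-kb windows while each window stays at or above a CPM threshold and does
not enter the body of a downstream expressed same-strand gene; extensions
of ≥ 12 kb become DoG calls. A *high-stringency* tier additionally requires
mean CPM > 1.5 over the 30–45 kb interval downstream of the TES (windows
7–9 of a 5-kb grid). Matched non-DoG control sets are built by greedy
nearest-neighbor matching (without replacement) in standardized
(log₁₀ length, log₁₀ expression) space.

**Replication timing.** Repli-seq early/late coverage gives the RT track
log₂((E+ε)/(L+ε)) after CPM normalization; early/late domains are segmented
by the sign of the smoothed RT with short runs merged away, and DoG genes
are related to early→late boundaries (distance in the direction of
transcription, direction of readthrough across domains, peak–late-region
intersection).

**Supporting statistics.** ChIP-Rx spike-in scale factors (inversely
proportional to exogenous-genome read counts), RNAPII pausing index
(TSS-window density over gene-body density, with isoform selection),
moving-average log₂ fold change over length-ordered genes (window of 250
genes each side), the readthrough detectability limit (elongation rate ×
treatment time, e.g. 1 kb/min × 240 min = 240 kb), Bliss-independence
synergy (Δ = predicted − observed effect with predicted = d₁ + d₂ − d₁d₂;
negative Δ = synergy) and the caliper tumor-volume formula (π/6)·D·d².

**Synthetic data.** `readthru.simulate` generates genomes, read sets and
Repli-seq tracks with known truth: log-spread gene lengths and expression,
condition-dependent 5′-tilted read densities, planted DoG genes with
exponentially decaying downstream coverage, T>C labels on a nascent
fraction, spike-in reads, and early/late replication domains with optional
late-region rescue.

## Worked example

```python
import numpy as np
from readthru import (SimulationConfig, simulate_genome, simulate_reads,
                      split_exonic, split_nascent, select_longest_decile,
                      metagene_profile, elongation_index, call_dogs,
                      high_stringency_filter)
from readthru.io import bin_coverage
from readthru.pipeline import stranded_tracks

cfg = SimulationConfig(n_genes=300, seed=1)
genes, chrom_sizes, truth = simulate_genome(cfg)

for cond in ("DMSO", "SN38+JQ1"):
    reads = simulate_reads(genes, truth, cfg, cond)
    nascent = split_nascent(reads).positive
    track = bin_coverage(nascent, 500, chrom_sizes)
    prof = metagene_profile(track, select_longest_decile(genes))
    print(cond, "SLAM index:", round(elongation_index(prof, "SLAM").slope, 2))

reads = simulate_reads(genes, truth, cfg, "SN38+JQ1")
nonexonic = split_exonic(reads, genes).negative
tracks = stranded_tracks(nonexonic, 500, chrom_sizes)
expressed = [g for g, ok in zip(genes, truth["fpkm"] >= 1.0) if ok]
calls = call_dogs(tracks, expressed)
hs = high_stringency_filter(calls)
true_dogs = set(truth.loc[truth["is_dog"], "gene_id"])
called = {c.gene_id for c in calls}
print(f"{len(calls)} DoG calls ({len(hs)} high-stringency), "
      f"recall {len(called & true_dogs) / len(true_dogs):.2f}, "
      f"median extent {int(np.median([c.dog_length for c in calls]))} bp")
```

prints

```
DMSO SLAM index: -0.11
SN38+JQ1 SLAM index: -68.76
56 DoG calls (56 high-stringency), recall 0.97, median extent 79000 bp
```

The untreated SLAM index is near zero (flat nascent coverage); under the
elongation-blocking combination it drops sharply (5′ accumulation). The DoG
caller recovers 97% of the planted readthrough genes, with readthrough
extents on the scale of the configured 50-kb decay length.

A command-line interface mirrors the library
(`readthru simulate|classify|metagene|dogs|bliss|run`), and
`readthru run --config analysis.yaml --outdir out/` executes the whole
chain, writing the annotation, truth table, DoG calls, control pairs and a
machine-readable `summary.json` that is byte-identical across reruns with
the same seed.

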