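"""Synthetic genomes, read sets and Repli-seq tracks with known ground truth.

The generator emulates the observable consequences of transcription-
elongation inhibition rather than the underlying mechanism: each treatment
condition is a small set of effect dials —

* ``elongation_block`` tilts within-gene nascent read density linearly
  toward the TSS (a 5'-shifted metagene),
* ``dog_gain`` scales readthrough (downstream-of-gene, DoG) read emission
  for the planted DoG gene subset, whose downstream coverage decays
  exponentially with scale ``dog_decay_length``,
* ``depth_factor`` scales total library depth,
* ``repli_factor`` / ``late_rescue`` scale Repli-seq coverage globally and
  in late-replicating domains respectively.

A single integer seed fixes the entire output stream; per-condition streams
are derived deterministically so conditions can be generated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import CoverageTrack, GeneModel, ReadRecord


@dataclass(frozen=True)
class ConditionEffect:
    """Effect dials for one treatment condition."""

    elongation_block: float = 0.0  # 5'-tilt strength in [0, 1]
    dog_gain: float = 0.0          # readthrough emission multiplier in [0, 1]
    depth_factor: float = 1.0      # library depth multiplier
    repli_factor: float = 1.0      # Repli-seq depth multiplier
    late_rescue: float = 1.0       # late-domain L-coverage multiplier

    def __post_init__(self) -> None:
        if not 0.0 <= self.elongation_block <= 1.0:
            raise ValueError("elongation_block must be in [0, 1]")
        if self.dog_gain < 0 or self.depth_factor < 0:
            raise ValueError("dog_gain and depth_factor must be >= 0")


def default_conditions() -> dict[str, ConditionEffect]:
    """TOP1-poison / BET-inhibitor treatment panel.

    The TOP1 poison (SN38) blocks elongation and induces readthrough; the
    BET inhibitor (JQ1) alone mainly lowers output; the combination
    maximizes readthrough and partially rescues late replication.
    """
    return {
        "DMSO": ConditionEffect(),
        "JQ1": ConditionEffect(elongation_block=0.0, dog_gain=0.1, depth_factor=0.7),
        "SN38": ConditionEffect(elongation_block=0.5, dog_gain=0.5, repli_factor=0.5),
        "SN38+JQ1": ConditionEffect(
            elongation_block=0.5, dog_gain=1.0, depth_factor=0.9,
            repli_factor=0.5, late_rescue=1.5,
        ),
    }


@dataclass
class SimulationConfig:
    """All knobs for one synthetic study.

    Gene lengths and expression are log-normal (log-spread, as for real
    transcriptomes); a ``dog_fraction`` of genes is planted as readthrough-
    prone. Scales are chosen for a scaled-down genome: hundreds of genes on
    tens of megabases with ~2,000 reads per gene, preserving the per-gene
    statistics of a full-size library.
    """

    n_genes: int = 300
    n_chroms: int = 2
    chrom_length: int = 25_000_000
    # gene geometry
    length_meanlog: float = float(np.log(15_000))
    length_sdlog: float = 0.8
    min_gene_length: int = 1_500
    gap_meanlog: float = float(np.log(80_000))
    gap_sdlog: float = 0.5
    exon_size: int = 250
    exon_spacing: int = 4_000
    # expression
    fpkm_meanlog: float = float(np.log(10.0))
    fpkm_sdlog: float = 0.8
    # readthrough
    dog_fraction: float = 0.2
    dog_decay_length: float = 50_000.0
    dog_read_fraction: float = 0.5   # DoG reads per gene read at dog_gain = 1
    dog_near_boundary: bool = False  # plant DoG genes just upstream of early->late borders
    # reads
    mean_reads_per_gene: int = 2_000
    read_length: int = 100
    noise_fraction: float = 0.002    # uniform intergenic background
    nascent_fraction: float = 0.4
    tc_rate: float = 0.02            # conversions per labeled-base opportunity
    u_content: float = 0.25
    spikein_reads: int = 50_000
    spikein_chrom: str = "spike_chr1"
    spikein_chrom_length: int = 1_000_000
    # replication timing
    domain_min_length: int = 800_000
    domain_max_length: int = 2_000_000
    repli_bin_size: int = 10_000
    repli_depth_high: float = 20.0   # mean reads/bin, matching phase
    repli_depth_low: float = 4.0     # mean reads/bin, opposite phase
    conditions: dict[str, ConditionEffect] = field(default_factory=default_conditions)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("dog_fraction", self.dog_fraction),
            ("nascent_fraction", self.nascent_fraction),
            ("noise_fraction", self.noise_fraction),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    def rng(self, *stream: str) -> np.random.Generator:
        """Deterministic per-stream generator derived from the master seed."""
        keys = [zlib.crc32(s.encode()) & 0x7FFFFFFF for s in stream]
        return np.random.default_rng([self.seed & 0x7FFFFFFF, *keys])

    @property
    def chrom_sizes(self) -> dict[str, int]:
        sizes = {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}
        sizes[self.spikein_chrom] = self.spikein_chrom_length
        return sizes

    def target_chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


def replication_domains(cfg: SimulationConfig) -> dict[str, list[tuple[int, int, str]]]:
    """Alternating early/late replication domains tiling each chromosome.

    Derived only from the config seed, so read simulation and Repli-seq
    simulation see identical domains without passing state around.
    """
    rng = cfg.rng("domains")
    out: dict[str, list[tuple[int, int, str]]] = {}
    for chrom in cfg.target_chroms():
        size = cfg.chrom_length
        label = "early" if rng.random() < 0.5 else "late"
        pos, segs = 0, []
        while pos < size:
            seg_len = int(rng.uniform(cfg.domain_min_length, cfg.domain_max_length))
            end = min(pos + seg_len, size)
            segs.append((pos, end, label))
            label = "late" if label == "early" else "early"
            pos = end
        out[chrom] = segs
    return out


def _domain_at(domains: list[tuple[int, int, str]], pos: int) -> str:
    for s, e, lab in domains:
        if s <= pos < e:
            return lab
    return domains[-1][2]


def _make_exons(start: int, end: int, cfg: SimulationConfig,
                rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    length = end - start
    n_exons = max(1, length // cfg.exon_spacing)
    exons = []
    for i in range(n_exons):
        seg0 = start + i * length // n_exons
        seg1 = start + (i + 1) * length // n_exons
        ex_len = min(cfg.exon_size, seg1 - seg0)
        off = int(rng.integers(0, max(1, (seg1 - seg0) - ex_len + 1)))
        exons.append((seg0 + off, seg0 + off + ex_len))
    return tuple(exons)


def simulate_genome(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, int], pd.DataFrame]:
    """Place non-overlapping genes, assign expression, DoG status and
    replication domains.

    Returns the gene models, the chromosome-size map (including the
    spike-in chromosome) and a per-gene truth table with columns
    ``gene_id, chrom, strand, start, end, length, fpkm, is_dog, domain,
    dist_next_same_strand``.
    """
    rng = cfg.rng("genome")
    domains = replication_domains(cfg)
    per_chrom = np.array_split(np.arange(cfg.n_genes), cfg.n_chroms)
    genes: list[GeneModel] = []
    rows = []
    gi = 0
    for ci, idx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = 0
        for _ in idx:
            gap = int(rng.lognormal(cfg.gap_meanlog, cfg.gap_sdlog))
            length = max(cfg.min_gene_length,
                         int(rng.lognormal(cfg.length_meanlog, cfg.length_sdlog)))
            start = pos + gap
            end = start + length
            if end > cfg.chrom_length:
                raise ValueError(
                    f"genome too small to place {cfg.n_genes} genes; "
                    f"increase chrom_length (> {cfg.chrom_length})"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{gi:05d}"
            genes.append(GeneModel(
                gene_id=gene_id, isoform_id=f"{gene_id}.1", chrom=chrom,
                strand=strand, start=start, end=end,
                exons=_make_exons(start, end, cfg, rng),
            ))
            fpkm = float(rng.lognormal(cfg.fpkm_meanlog, cfg.fpkm_sdlog))
            rows.append({
                "gene_id": gene_id, "chrom": chrom, "strand": strand,
                "start": start, "end": end, "length": length, "fpkm": fpkm,
            })
            pos = end
            gi += 1
    truth = pd.DataFrame(rows)
    truth["domain"] = [
        _domain_at(domains[g.chrom], g.tss) for g in genes
    ]
    truth["dist_next_same_strand"] = _next_same_strand_distance(genes, cfg)
    truth["is_dog"] = _assign_dogs(genes, truth, domains, cfg, rng)
    return genes, cfg.chrom_sizes, truth


def _next_same_strand_distance(genes: list[GeneModel], cfg: SimulationConfig) -> list[float]:
    """Room available for readthrough: bp from each TES to the next
    same-strand gene body downstream (chromosome end if none)."""
    out = []
    for g in genes:
        same = [h for h in genes if h.chrom == g.chrom and h.strand == g.strand and h is not g]
        if g.strand == "+":
            nxt = min((h.start for h in same if h.start >= g.end), default=cfg.chrom_length)
            out.append(float(nxt - g.end))
        else:
            nxt = max((h.end for h in same if h.end <= g.start), default=0)
            out.append(float(g.start - nxt))
    return out


def _assign_dogs(genes, truth, domains, cfg, rng) -> np.ndarray:
    n_dog = int(round(cfg.dog_fraction * cfg.n_genes)) if cfg.dog_near_boundary else None
    is_dog = np.zeros(len(genes), dtype=bool)
    if cfg.dog_fraction == 0:
        return is_dog
    if not cfg.dog_near_boundary:
        return rng.random(len(genes)) < cfg.dog_fraction
    # plant DoGs on early-region genes closest (in transcription direction)
    # to the next early->late border
    dists = np.full(len(genes), np.inf)
    for i, g in enumerate(genes):
        if truth["domain"].iloc[i] != "early":
            continue
        segs = domains[g.chrom]
        if g.strand == "+":
            cands = [s for s, e, lab in segs if lab == "late" and s >= g.tes]
            if cands:
                dists[i] = min(cands) - g.tes
        else:
            cands = [e for s, e, lab in segs if lab == "late" and e <= g.tes]
            if cands:
                dists[i] = g.tes - max(cands)
    order = np.argsort(dists, kind="stable")
    is_dog[order[:n_dog]] = True
    return is_dog


def _tilted_positions(n: int, block: float, rng: np.random.Generator) -> np.ndarray:
    """Sample scaled gene-body positions u in [0, 1] with linear density
    1 + block*(1 - 2u): inverse-CDF of (1+b)u - b*u^2."""
    t = rng.random(n)
    if block == 0:
        return t
    b = block
    disc = (1 + b) ** 2 - 4 * b * t
    return ((1 + b) - np.sqrt(disc)) / (2 * b)


def simulate_reads(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    condition: str,
) -> list[ReadRecord]:
    """Draw one library for a condition.

    Per gene, reads fall along the body with density proportional to
    expression and a linear 5' tilt of strength ``elongation_block``; DoG
    genes additionally emit downstream reads with exponentially decaying
    offsets (truncated at the next same-strand gene body, where a
    readthrough polymerase would be read as that gene); a ``nascent_fraction``
    of gene-derived reads carries T>C conversions; background noise is
    uniform; spike-in reads are uniform on the spike-in chromosome.
    """
    if condition not in cfg.conditions:
        raise ValueError(f"condition {condition!r} not declared in config")
    eff = cfg.conditions[condition]
    rng = cfg.rng("reads", condition)
    w = (truth["fpkm"] * truth["length"]).to_numpy()
    n_total = cfg.mean_reads_per_gene * cfg.n_genes * eff.depth_factor
    lam = n_total * w / w.sum()
    reads: list[ReadRecord] = []
    sample_id = condition
    rl = cfg.read_length
    for i, g in enumerate(genes):
        n_gene = int(rng.poisson(lam[i]))
        span = max(1, g.length - rl)
        u = _tilted_positions(n_gene, eff.elongation_block, rng)
        if g.strand == "+":
            starts = g.start + (u * span).astype(int)
        else:
            starts = g.end - rl - (u * span).astype(int)
        tc = _tc_labels(n_gene, cfg, rng)
        for s, c in zip(starts, tc):
            reads.append(ReadRecord(g.chrom, int(s), int(s) + rl, g.strand,
                                    "target", int(c), sample_id))
        if truth["is_dog"].iloc[i] and eff.dog_gain > 0:
            n_dog = int(rng.poisson(lam[i] * cfg.dog_read_fraction * eff.dog_gain))
            offs = rng.exponential(cfg.dog_decay_length, n_dog)
            room = truth["dist_next_same_strand"].iloc[i] - rl
            offs = offs[offs < max(room, 0)]
            tc = _tc_labels(len(offs), cfg, rng)
            for off, c in zip(offs, tc):
                if g.strand == "+":
                    s = g.end + int(off)
                else:
                    s = g.start - int(off) - rl
                if s < 0 or s + rl > cfg.chrom_length:
                    continue
                reads.append(ReadRecord(g.chrom, s, s + rl, g.strand,
                                        "target", int(c), sample_id))
    n_noise = int(rng.poisson(cfg.noise_fraction * n_total))
    for _ in range(n_noise):
        chrom = cfg.target_chroms()[int(rng.integers(cfg.n_chroms))]
        s = int(rng.integers(0, cfg.chrom_length - rl))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(ReadRecord(chrom, s, s + rl, strand, "target", 0, sample_id))
    n_spike = int(rng.poisson(cfg.spikein_reads * eff.depth_factor))
    for _ in range(n_spike):
        s = int(rng.integers(0, cfg.spikein_chrom_length - rl))
        reads.append(ReadRecord(cfg.spikein_chrom, s, s + rl, ".", "spikein", 0, sample_id))
    return reads


def _tc_labels(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Conversion counts: a nascent_fraction of reads is labeled; labeled
    reads carry at least one detected conversion plus a Poisson count of
    additional ones (per-read, not per-site)."""
    tc = np.zeros(n, dtype=int)
    if n and cfg.nascent_fraction > 0:
        nascent = rng.random(n) < cfg.nascent_fraction
        mean_extra = cfg.tc_rate * (cfg.read_length - 1) * cfg.u_content
        tc[nascent] = 1 + rng.poisson(mean_extra, int(nascent.sum()))
    return tc


def simulate_repliseq(
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    condition: str,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Early (E) and late (L) S-phase coverage tracks.

    E coverage concentrates in early domains and L in late domains, each
    Poisson per bin. The condition's ``repli_factor`` scales both tracks
    (replication suppression); ``late_rescue`` multiplies L coverage inside
    late domains only (dormant-origin firing under the combination).
    """
    if condition not in cfg.conditions:
        raise ValueError(f"condition {condition!r} not declared in config")
    eff = cfg.conditions[condition]
    rng = cfg.rng("repliseq", condition)
    domains = replication_domains(cfg)
    bs = cfg.repli_bin_size
    e_counts: dict[str, np.ndarray] = {}
    l_counts: dict[str, np.ndarray] = {}
    for chrom in cfg.target_chroms():
        n_bins = -(-cfg.chrom_length // bs)
        centers = (np.arange(n_bins) + 0.5) * bs
        early_mask = np.zeros(n_bins, dtype=bool)
        for s, e, lab in domains[chrom]:
            if lab == "early":
                early_mask |= (centers >= s) & (centers < e)
        e_mean = np.where(early_mask, cfg.repli_depth_high, cfg.repli_depth_low)
        l_mean = np.where(early_mask, cfg.repli_depth_low, cfg.repli_depth_high)
        l_mean = np.where(~early_mask, l_mean * eff.late_rescue, l_mean)
        e_counts[chrom] = rng.poisson(e_mean * eff.repli_factor).astype(float)
        l_counts[chrom] = rng.poisson(l_mean * eff.repli_factor).astype(float)
    e_lib = int(sum(v.sum() for v in e_counts.values()))
    l_lib = int(sum(v.sum() for v in l_counts.values()))
    return (
        CoverageTrack(bs, e_counts, library_size=e_lib),
        CoverageTrack(bs, l_counts, library_size=l_lib),
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_annotation_gtf(genes: list[GeneModel], path) -> None:
    """Write gene models as Ensembl-dialect GTF (1-based closed on disk)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = (f'gene_id "{g.gene_id}"; transcript_id "{g.isoform_id}"; '
                     f'gene_biotype "{g.biotype or "protein_coding"}";')
            fh.write(f"{g.chrom}\tsim\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
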