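"""Downstream-of-gene (DoG) transcript calling and readthrough geometry.

A DoG call starts at a gene's TES and extends window by window in the
direction of transcription for as long as each window holds coverage at or
above a threshold and does not run into the body of a downstream expressed
same-strand gene. Calls shorter than a minimum length (default 12 kb, with
2-kb windows) are discarded. A high-stringency tier additionally requires
CPM > 1.5 averaged over the 30-45 kb interval downstream of the TES
(windows 7-9 of the 5-kb grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metagene import downstream_profile
from .model import CoverageTrack, GeneModel

HS_WINDOW = 5_000
HS_EXTENT = 100_000
HS_RANGE = (30_000, 45_000)
HS_CPM = 1.5


@dataclass
class DoGCall:
    gene_id: str
    chrom: str
    strand: str
    tes: int
    dog_length: int
    window_cpm: np.ndarray  # 5-kb window CPMs over 100 kb downstream
    tier: str = "standard"
    condition: str = ""
    truncated: bool = False  # downstream windows ran off the chromosome

    def interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.tes + 1, self.tes + 1 + self.dog_length
        return self.tes - self.dog_length, self.tes


def longest_isoform_per_gene(genes: list[GeneModel]) -> list[GeneModel]:
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.gene_id)
        if cur is None or (g.length, g.isoform_id) > (cur.length, cur.isoform_id):
            best[g.gene_id] = g
    return [best[k] for k in sorted(best)]


def _strand_track(coverage, strand: str) -> CoverageTrack:
    if isinstance(coverage, dict):
        return coverage[strand]
    return coverage


def call_dogs(
    coverage: CoverageTrack | dict[str, CoverageTrack],
    genes: list[GeneModel],
    min_dog_length: int = 12_000,
    window: int = 2_000,
    coverage_threshold: float = 0.1,
    condition: str = "",
) -> list[DoGCall]:
    """Call DoG transcripts from CPM coverage for a set of expressed genes.

    ``coverage`` is a single (unstranded) track or a ``{"+": track, "-":
    track}`` pair for stranded libraries; each gene is scored on its own
    strand. A window continues the extension iff its total CPM is at least
    ``coverage_threshold``; extension also stops at the body of the next
    expressed same-strand gene (opposite-strand genes do not stop it) and
    at chromosome ends. Overlapping annotations are resolved to the longest
    isoform per gene before calling.
    """
    genes = longest_isoform_per_gene(genes)
    bodies: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for g in genes:
        bodies.setdefault((g.chrom, g.strand), ([], []))
        bodies[(g.chrom, g.strand)][0].append(g.start)
        bodies[(g.chrom, g.strand)][1].append(g.end)
    bodies = {
        k: (
            np.array(sorted(v[0])),
            np.maximum.accumulate(np.array([e for _, e in sorted(zip(v[0], v[1]))])),
        )
        for k, v in bodies.items()
    }
    calls: list[DoGCall] = []
    for g in genes:
        track = _strand_track(coverage, g.strand)
        chrom_len = len(track.counts[g.chrom]) * track.bin_size
        starts, cummax_ends = bodies[(g.chrom, g.strand)]
        n_win = 0
        while True:
            s, e = g.downstream_interval(n_win * window, window)
            if s < 0 or e > chrom_len:
                break
            # overlap with any same-strand expressed gene body; the window
            # lies wholly outside the calling gene's own body, so no
            # self-exclusion is needed
            i = int(np.searchsorted(starts, e, side="left"))
            if i > 0 and cummax_ends[i - 1] > s:
                break
            if track.region_sum_cpm(g.chrom, s, e) < coverage_threshold:
                break
            n_win += 1
        dog_len = n_win * window
        if dog_len >= min_dog_length:
            prof = downstream_profile(track, [g], extent=HS_EXTENT, window=HS_WINDOW)
            wc = prof.iloc[0].to_numpy()
            calls.append(DoGCall(
                gene_id=g.gene_id, chrom=g.chrom, strand=g.strand, tes=g.tes,
                dog_length=dog_len, window_cpm=wc, tier="standard",
                condition=condition, truncated=bool(np.isnan(wc).any()),
            ))
    return calls


def high_stringency_filter(
    calls: list[DoGCall],
    cpm_threshold: float = HS_CPM,
    cpm_range: tuple[int, int] = HS_RANGE,
    per_window: bool = False,
) -> list[DoGCall]:
    """Keep calls with a high level of readthrough 30-45 kb past the TES.

    Default rule: mean window CPM over the 30-45 kb interval strictly above
    ``cpm_threshold`` (``per_window=True`` instead requires every window in
    the range to exceed it). Calls whose range windows are truncated by a
    chromosome end are excluded with a warning.
    """
    lo, hi = cpm_range[0] // HS_WINDOW, cpm_range[1] // HS_WINDOW
    kept, excluded = [], 0
    for c in calls:
        seg = c.window_cpm[lo:hi]
        if np.isnan(seg).any():
            excluded += 1
            continue
        ok = (seg > cpm_threshold).all() if per_window else seg.mean() > cpm_threshold
        if ok:
            kept.append(DoGCall(c.gene_id, c.chrom, c.strand, c.tes, c.dog_length,
                                c.window_cpm, "high_stringency", c.condition, c.truncated))
    if excluded:
        warnings.warn(f"{excluded} DoG calls excluded: high-stringency window "
                      "truncated by chromosome end", stacklevel=2)
    return kept


@dataclass
class ControlSet:
    """DoG genes paired with expressed non-DoG genes of similar length and
    expression (greedy nearest neighbor without replacement in standardized
    log10-length x log10-FPKM space)."""

    pairs: pd.DataFrame  # dog_gene_id, control_gene_id, distance


def match_controls(
    dog_genes: pd.DataFrame,
    pool: pd.DataFrame,
    seed: int = 0,
) -> ControlSet:
    """Match each DoG gene to an expressed non-DoG control.

    Both frames need ``gene_id``, ``length`` and ``fpkm`` columns; the pool
    must be at least as large as the DoG set. DoG genes are processed in a
    seeded random order; each control is used at most once.
    """
    if len(pool) < len(dog_genes):
        raise ValueError(
            f"control pool ({len(pool)}) smaller than DoG set ({len(dog_genes)})"
        )
    overlap = set(dog_genes["gene_id"]) & set(pool["gene_id"])
    if overlap:
        raise ValueError(f"control pool contains DoG genes: {sorted(overlap)[:5]}")
    both = pd.concat([dog_genes, pool])
    feats = np.log10(both[["length", "fpkm"]].to_numpy(dtype=float))
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    z_dog, z_pool = z[: len(dog_genes)], z[len(dog_genes):]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dog_genes))
    taken = np.zeros(len(pool), dtype=bool)
    rows = []
    for i in order:
        d = np.linalg.norm(z_pool - z_dog[i], axis=1)
        d[taken] = np.inf
        j = int(np.argmin(d))
        taken[j] = True
        rows.append({
            "dog_gene_id": dog_genes["gene_id"].iloc[i],
            "control_gene_id": pool["gene_id"].iloc[j],
            "distance": float(d[j]),
        })
    return ControlSet(pd.DataFrame(rows).sort_values("dog_gene_id").reset_index(drop=True))


def distance_to_next_expressed_gene(
    gene: GeneModel, expressed_genes: list[GeneModel]
) -> float:
    """bp from the TES to the nearest expressed-gene boundary downstream in
    the direction of transcription, any strand; 0 if a gene overlaps the
    TES-downstream region; inf if none on the chromosome."""
    tes = gene.tes
    best = np.inf
    for h in expressed_genes:
        if h.chrom != gene.chrom or (h.gene_id == gene.gene_id):
            continue
        if gene.strand == "+":
            if h.end > tes:
                best = min(best, max(0, h.start - tes))
        else:
            if h.start < tes:
                best = min(best, max(0, tes - h.end))
    return float(best)


def readthrough_detectability_limit(rate_kb_per_min: float, duration_min: float) -> float:
    """Maximum gene length (kb) at which readthrough can appear: a
    polymerase released at the pausing site must first traverse the gene, so
    at elongation rate r for time t only genes shorter than r*t can show
    readthrough."""
    if rate_kb_per_min <= 0:
        raise ValueError("rate must be > 0")
    if duration_min < 0:
        raise ValueError("duration must be >= 0")
    return rate_kb_per_min * duration_min


def dog_overlap(set_a: set[str], set_b: set[str]) -> tuple[int, int, int, float]:
    """Venn counts (A only, A and B, B only) and the fraction of A also in B."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    frac = len(inter) / len(a) if a else float("nan")
    return len(a - b), len(inter), len(b - a), frac
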