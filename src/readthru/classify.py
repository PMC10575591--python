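"""Read classification (exonic/nonexonic, nascent/background) and ChIP-Rx
spike-in scale factors.

Intronic ("nonexonic") reads proxy nascent transcription because introns
are excised and degraded cotranscriptionally; reads carrying T>C
conversions after 4sU metabolic labeling are nascent by construction. Both
axes are computed here so downstream metagene profiles can use either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GeneModel, ReadRecord


@dataclass
class ClassifiedReads:
    """Disjoint partition of target-genome reads along one axis."""

    positive: list[ReadRecord]
    negative: list[ReadRecord]
    axis: str  # "exonic" or "nascent"

    @property
    def counts(self) -> dict[str, int]:
        return {self.axis: len(self.positive), f"non_{self.axis}": len(self.negative)}


def _exon_arrays(genes: list[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merged exon-union intervals per chromosome (strand-agnostic)."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).extend(g.exons)
    out = {}
    for chrom, blocks in per_chrom.items():
        merged: list[list[int]] = []
        for s, e in sorted(blocks):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        out[chrom] = (starts, ends)
    return out


def split_exonic(
    reads: list[ReadRecord],
    genes: list[GeneModel],
    min_overlap: int = 1,
) -> ClassifiedReads:
    """Partition reads into exonic vs nonexonic.

    A read is exonic iff it overlaps at least ``min_overlap`` bp of the
    exon union over all isoforms of all genes, regardless of strand (library
    chemistry strandedness is not assumed). Spike-in reads are ignored.
    """
    exons = _exon_arrays(genes)
    exonic, nonexonic = [], []
    for r in reads:
        if r.genome != "target":
            continue
        hit = False
        if r.chrom in exons:
            starts, ends = exons[r.chrom]
            # candidate exons: those starting before the read ends
            i = int(np.searchsorted(starts, r.end - min_overlap, side="right")) - 1
            # walk left while exons could still overlap
            while i >= 0 and ends[i] > r.start:
                if min(r.end, ends[i]) - max(r.start, starts[i]) >= min_overlap:
                    hit = True
                    break
                i -= 1
        (exonic if hit else nonexonic).append(r)
    return ClassifiedReads(exonic, nonexonic, axis="exonic")


def split_nascent(
    reads: list[ReadRecord],
    min_conversions: int = 1,
    snp_mask: set[tuple[str, int]] | None = None,
) -> ClassifiedReads:
    """Partition reads into nascent (T>C labeled) vs background.

    A read is nascent iff its conversion count, after subtracting
    conversions at masked SNP positions when positional data are carried,
    is at least ``min_conversions``. Per-read counts here carry no
    positions, so the mask is accepted for interface compatibility and
    applied only when a read exposes positional conversions.
    """
    if min_conversions < 1:
        raise ValueError("min_conversions must be >= 1")
    nascent, background = [], []
    for r in reads:
        if r.genome != "target":
            continue
        tc = r.tc_conversions
        positions = getattr(r, "tc_positions", None)
        if snp_mask and positions is not None:
            tc -= sum(1 for p in positions if (r.chrom, p) in snp_mask)
        (nascent if tc >= min_conversions else background).append(r)
    return ClassifiedReads(nascent, background, axis="nascent")


def chiprx_scale_factor(spikein_counts: dict[str, int]) -> dict[str, float]:
    """Per-sample spike-in normalization factors.

    Each factor is inversely proportional to the sample's spike-in
    (exogenous-genome) read count; the proportionality constant is the
    minimum spike-in count across samples, so the smallest-spike sample
    gets factor 1 and all factors lie in (0, 1].
    """
    if not spikein_counts:
        raise ValueError("no samples given")
    if any(c <= 0 for c in spikein_counts.values()):
        bad = [s for s, c in spikein_counts.items() if c <= 0]
        raise ValueError(f"spike-in normalization undefined for zero counts: {bad}")
    c = min(spikein_counts.values())
    return {s: c / n for s, n in spikein_counts.items()}


def count_spikein(reads: list[ReadRecord]) -> int:
    return sum(1 for r in reads if r.genome == "spikein")


def spikein_cpm_track(reads: list[ReadRecord], bin_size: int,
                      chrom_sizes: dict[str, int]):
    """Target-genome coverage expressed per million spike-in reads.

    Dividing by the spike-in count instead of the target library size makes
    the track invariant to multiplying a sample's material (target and
    spike-in reads alike) by any constant — the quantitative ChIP-Rx
    normalization property.
    """
    from .io import bin_coverage
    from .model import CoverageTrack

    n_spike = count_spikein(reads)
    if n_spike == 0:
        raise ValueError("spike-in normalization undefined: no spike-in reads")
    t = bin_coverage([r for r in reads if r.genome == "target"], bin_size, chrom_sizes)
    return CoverageTrack(bin_size, t.counts, library_size=n_spike)
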