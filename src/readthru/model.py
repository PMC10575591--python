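"""Shared genomic data model and coordinate conventions.

All coordinates are 0-based half-open ``[start, end)``. GTF input (1-based
closed) is converted on ingestion and never handled internally. The
transcription start site (TSS) of a ``+`` strand gene is ``start``; for a
``-`` strand gene it is ``end - 1``. The transcription end site (TES) is the
opposite terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True, slots=True)
class GeneModel:
    """One gene/isoform with strand-aware termini and exon blocks.

    Invariants: ``start < end``; exons are disjoint, sorted and contained in
    ``[start, end)``.
    """

    gene_id: str
    isoform_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: start must be < end ({self.start} >= {self.end})"
            )
        prev = self.start
        for s, e in self.exons:
            if s < prev or e > self.end or s >= e:
                raise ValueError(
                    f"{self.gene_id}: exons must be sorted, disjoint and "
                    f"contained in [{self.start}, {self.end})"
                )
            prev = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def downstream_interval(self, offset: int, extent: int) -> tuple[int, int]:
        """Genomic interval covering ``[offset, offset+extent)`` bp past the
        TES in the direction of transcription (may have negative start; the
        caller clips)."""
        if self.strand == "+":
            return self.end + offset, self.end + offset + extent
        return self.start - offset - extent, self.start - offset


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One aligned read interval.

    ``genome`` is ``"target"`` or ``"spikein"``; spike-in reads never enter
    target-genome profiles. ``tc_conversions`` counts T>C mismatches called
    for the read (0 for unlabeled/background reads).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    genome: str = "target"
    tc_conversions: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"read start must be < end ({self.start} >= {self.end})")
        if self.tc_conversions < 0:
            raise ValueError("tc_conversions must be non-negative")
        if self.genome not in ("target", "spikein"):
            raise ValueError(f"unknown genome label {self.genome!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class CoverageTrack:
    """Fixed-bin read counts per chromosome.

    CPM for a bin is ``count * 1e6 / library_size * scale_factor``; the
    scale factor defaults to 1 and carries spike-in normalization when set.
    """

    def __init__(
        self,
        bin_size: int,
        counts: dict[str, np.ndarray],
        library_size: int,
        scale_factor: float = 1.0,
    ):
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.bin_size = int(bin_size)
        self.counts = {c: np.asarray(v, dtype=float) for c, v in counts.items()}
        for c, v in self.counts.items():
            if (v < 0).any():
                raise ValueError(f"negative counts on {c}")
        self.library_size = int(library_size)
        self.scale_factor = float(scale_factor)

    @property
    def chroms(self) -> list[str]:
        return list(self.counts)

    def cpm(self, chrom: str) -> np.ndarray:
        if self.library_size == 0:
            raise ValueError("CPM undefined: library size is zero")
        return self.counts[chrom] * (1e6 / self.library_size) * self.scale_factor

    def total_count(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def region_sum_cpm(self, chrom: str, start: int, end: int) -> float:
        """Total CPM attributed to ``[start, end)``, weighting boundary bins
        by their overlap fraction."""
        if end <= start:
            return 0.0
        vals = self.cpm(chrom)
        n = len(vals)
        lo = max(0, start // self.bin_size)
        hi = min(n, -(-end // self.bin_size))
        total = 0.0
        for i in range(lo, hi):
            b0, b1 = i * self.bin_size, (i + 1) * self.bin_size
            ov = min(end, b1) - max(start, b0)
            if ov > 0:
                total += vals[i] * ov / self.bin_size
        return total

    def region_density(self, chrom: str, start: int, end: int) -> float:
        """Mean CPM per bp over ``[start, end)``."""
        if end <= start:
            raise ValueError("empty region")
        return self.region_sum_cpm(chrom, start, end) / (end - start)

    def with_scale(self, scale_factor: float) -> "CoverageTrack":
        return CoverageTrack(self.bin_size, self.counts, self.library_size, scale_factor)


@dataclass
class SampleTable:
    """Sample metadata: one row per sequencing library."""

    table: "object"  # pandas.DataFrame with sample_id, condition, replicate, assay, path

    REQUIRED = ("sample_id", "condition", "replicate", "assay")

    def __post_init__(self) -> None:
        cols = set(self.table.columns)
        missing = [c for c in self.REQUIRED if c not in cols]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_id: {sorted(set(dup))}")
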