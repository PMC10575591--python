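"""Readers/writers for GTF, BED6/BED12, bedGraph and sample tables.

GTF parsing goes through :mod:`pyranges` (Ensembl dialect); BED and
bedGraph are plain TSV handled with pandas. All records come back in the
internal 0-based half-open convention.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CoverageTrack, GeneModel, ReadRecord, SampleTable


def _merge_blocks(blocks: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def read_annotation(path: str | Path, biotype_filter: str | None = None) -> list[GeneModel]:
    """Read gene models from a GTF or BED12 file.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    ``biotype_filter`` keeps only records with a matching biotype (GTF
    ``gene_biotype`` attribute; BED12 has no biotype so the filter is a
    no-op there). Exons are merged per isoform.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        genes = _read_gtf(path)
    else:
        genes = _read_bed12(path)
    if biotype_filter is not None:
        genes = [g for g in genes if g.biotype == biotype_filter]
    if not genes:
        warnings.warn(f"no gene models read from {path}", stacklevel=2)
    return genes


def _read_gtf(path: Path) -> list[GeneModel]:
    import pyranges as pr

    try:
        df = pr.read_gtf(str(path)).df
    except Exception as exc:  # pragma: no cover - library error path
        raise ValueError(f"malformed GTF {path}: {exc}") from exc
    if df.empty:
        return []
    tx = df[df.Feature == "transcript"]
    ex = df[df.Feature == "exon"]
    biotype_col = "gene_biotype" if "gene_biotype" in df.columns else None
    out: list[GeneModel] = []
    exon_groups = (
        {k: list(zip(v.Start, v.End)) for k, v in ex.groupby("transcript_id")}
        if not ex.empty
        else {}
    )
    source = tx if not tx.empty else df[df.Feature == "gene"]
    for row in source.itertuples():
        iso = getattr(row, "transcript_id", None) or row.gene_id
        out.append(
            GeneModel(
                gene_id=row.gene_id,
                isoform_id=iso,
                chrom=str(row.Chromosome),
                strand=row.Strand,
                start=int(row.Start),
                end=int(row.End),
                exons=_merge_blocks(exon_groups.get(iso, [])),
                biotype=(getattr(row, biotype_col) if biotype_col else "") or "",
            )
        )
    return out


_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def _read_bed12(path: Path) -> list[GeneModel]:
    out: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5]
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED12 line: {exc}") from exc
            exons = _merge_blocks([(start + o, start + o + sz) for o, sz in zip(starts, sizes)])
            out.append(
                GeneModel(
                    gene_id=name, isoform_id=name, chrom=chrom, strand=strand,
                    start=start, end=end, exons=exons, biotype="",
                )
            )
    return out


def read_intervals(
    path: str | Path,
    genome_labels: dict[str, str] | None = None,
    sample_id: str = "",
) -> list[ReadRecord]:
    """Read aligned read intervals from a BED6 file.

    ``genome_labels`` maps chromosome-name prefixes to ``{"target",
    "spikein"}``; chromosomes matching no prefix default to ``target`` when
    the map is empty, otherwise they must match a declared prefix. A 7th
    integer column, when present, is taken as the per-read T>C conversion
    count.
    """
    genome_labels = genome_labels or {}
    records: list[ReadRecord] = []
    unknown: set[str] = set()
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED requires >=3 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            tc = int(f[6]) if len(f) > 6 and f[6] != "" else 0
            genome = _genome_of(chrom, genome_labels, unknown)
            records.append(
                ReadRecord(chrom=chrom, start=start, end=end, strand=strand,
                           genome=genome, tc_conversions=tc, sample_id=sample_id)
            )
    if unknown:
        raise ValueError(f"chromosomes match no declared genome prefix: {sorted(unknown)}")
    return records


def _genome_of(chrom: str, labels: dict[str, str], unknown: set[str]) -> str:
    if not labels:
        return "target"
    for prefix, genome in labels.items():
        if chrom.startswith(prefix):
            return genome
    # prefixes may declare only the spike-in genome; treat the rest as target
    if "target" not in labels.values():
        return "target"
    unknown.add(chrom)
    return "target"


def write_intervals(reads: list[ReadRecord], path: str | Path) -> None:
    """Write reads as BED6 plus a 7th T>C conversion-count column."""
    with open(Path(path), "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\t{r.tc_conversions}\n")


def bin_coverage(
    reads: list[ReadRecord],
    bin_size: int,
    chrom_sizes: dict[str, int],
    attribution: str = "midpoint",
    scale_factor: float = 1.0,
) -> CoverageTrack:
    """Bin target-genome reads into a :class:`CoverageTrack`.

    With the default midpoint attribution each read adds 1 to the single bin
    containing its midpoint, so bin sums conserve read counts exactly. The
    ``overlap`` mode instead adds the per-bin overlap fraction of the read.
    Reads beyond the declared chromosome size are clipped with a warning.
    ``library_size`` is the number of target reads regardless of attribution.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if attribution not in ("midpoint", "overlap"):
        raise ValueError(f"unknown attribution {attribution!r}")
    counts = {
        c: np.zeros(-(-size // bin_size), dtype=float) for c, size in chrom_sizes.items()
    }
    target = [r for r in reads if r.genome == "target"]
    clipped = 0
    for r in target:
        if r.chrom not in counts:
            raise ValueError(f"read on undeclared chromosome {r.chrom!r}")
        vec = counts[r.chrom]
        size = chrom_sizes[r.chrom]
        start, end = r.start, min(r.end, size)
        if r.end > size:
            clipped += 1
        if attribution == "midpoint":
            mid = min((r.start + r.end) // 2, size - 1)
            vec[mid // bin_size] += 1.0
        else:
            length = r.end - r.start
            for b in range(start // bin_size, -(-end // bin_size)):
                ov = min(end, (b + 1) * bin_size) - max(start, b * bin_size)
                if ov > 0:
                    vec[b] += ov / length
    if clipped:
        warnings.warn(f"{clipped} reads extended beyond chromosome end and were clipped",
                      stacklevel=2)
    return CoverageTrack(bin_size, counts, library_size=len(target), scale_factor=scale_factor)


def write_bedgraph(track: CoverageTrack, path: str | Path, values: str = "count") -> None:
    """Write a track as bedGraph (``count`` or ``cpm`` values); zero bins
    are omitted as is conventional."""
    with open(Path(path), "w") as fh:
        for chrom in track.chroms:
            vec = track.counts[chrom] if values == "count" else track.cpm(chrom)
            for i, v in enumerate(vec):
                if v != 0:
                    fh.write(f"{chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:g}\n")


def read_bedgraph(
    path: str | Path, bin_size: int, chrom_sizes: dict[str, int], library_size: int
) -> CoverageTrack:
    """Read a bedGraph written on a fixed grid back into a track."""
    counts = {c: np.zeros(-(-s // bin_size), dtype=float) for c, s in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    for row in df.itertuples():
        if row.start % bin_size:
            raise ValueError(f"bedGraph interval not on the {bin_size}-bp grid: {row}")
        counts[row.chrom][row.start // bin_size] = row.value
    return CoverageTrack(bin_size, counts, library_size=library_size)


def read_sample_table(path: str | Path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))
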