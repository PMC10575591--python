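"""Replication timing from Repli-seq E/L coverage: RT profiles, early/late
segmentation, and the geometry of readthrough relative to RT boundaries.

Replication timing (RT) is the per-bin log2 ratio of CPM-normalized early
(E) over late (L) S-phase coverage, with a pseudocount. Early/late domains
are segmented by the sign of the smoothed RT with short runs merged away —
a transparent surrogate for wavelet-based segmenters that yields the same
deliverables (region labels and boundary positions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CoverageTrack, GeneModel


@dataclass
class ReplicationTrack:
    E: CoverageTrack
    L: CoverageTrack
    rt: dict[str, np.ndarray]  # smoothed log2((E_cpm+eps)/(L_cpm+eps))
    epsilon: float

    @property
    def bin_size(self) -> int:
        return self.E.bin_size


@dataclass
class ReplicationSegments:
    """Alternating early/late intervals tiling each chromosome."""

    segments: dict[str, list[tuple[int, int, str]]]
    min_segment_length: int

    def boundaries(self, chrom: str) -> list[int]:
        segs = self.segments[chrom]
        return [seg[1] for seg in segs[:-1]]

    def label_at(self, chrom: str, pos: int) -> str | None:
        for s, e, lab in self.segments.get(chrom, []):
            if s <= pos < e:
                return lab
        return None


def rt_profile(
    E: CoverageTrack,
    L: CoverageTrack,
    epsilon: float = 0.5,
    smoothing_bp: int = 50_000,
) -> ReplicationTrack:
    """log2 E/L replication-timing track.

    Both tracks are CPM-normalized (so sequencing depth cancels), offset by
    the pseudocount ``epsilon`` (CPM units) and log-ratioed, then mean-
    smoothed over ``smoothing_bp``. Positive RT means earlier replication.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if E.bin_size != L.bin_size or set(E.chroms) != set(L.chroms):
        raise ValueError("E and L tracks must share binning and chromosomes")
    rt: dict[str, np.ndarray] = {}
    w = max(1, smoothing_bp // E.bin_size)
    for chrom in E.chroms:
        e, l = E.cpm(chrom), L.cpm(chrom)
        if len(e) != len(l):
            raise ValueError(f"bin count mismatch on {chrom}")
        raw = np.log2((e + epsilon) / (l + epsilon))
        rt[chrom] = (
            pd.Series(raw).rolling(w, center=True, min_periods=1).mean().to_numpy()
        )
    return ReplicationTrack(E=E, L=L, rt=rt, epsilon=epsilon)


def segment_rt(track: ReplicationTrack, min_segment_length: int = 100_000) -> ReplicationSegments:
    """Early/late segmentation by thresholding smoothed RT at 0.

    Runs shorter than ``min_segment_length`` are merged into a flanking
    segment (the longer neighbor wins; ties go to the earlier segment);
    boundaries land on bin edges.
    """
    bs = track.bin_size
    out: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, rt in track.rt.items():
        if len(rt) == 0 or not np.isfinite(rt).any():
            warnings.warn(f"RT undefined on {chrom}; skipped", stacklevel=2)
            continue
        labels = np.where(rt >= 0, "early", "late")
        runs = _runs(labels)
        runs = _merge_short(runs, min_bins=-(-min_segment_length // bs))
        out[chrom] = [(s * bs, e * bs, lab) for s, e, lab in runs]
    return ReplicationSegments(segments=out, min_segment_length=min_segment_length)


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, str(labels[start])))
            start = i
    return runs


def _merge_short(runs: list[tuple[int, int, str]], min_bins: int) -> list[tuple[int, int, str]]:
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        lengths = [r[1] - r[0] for r in runs]
        short = [i for i, ln in enumerate(lengths) if ln < min_bins]
        if not short:
            break
        i = min(short, key=lambda k: (lengths[k], k))
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            left, right = lengths[i - 1], lengths[i + 1]
            j = i - 1 if left >= right else i + 1
        runs[i][2] = runs[j][2]
        # coalesce equal-label neighbors
        merged = [runs[0]]
        for r in runs[1:]:
            if r[2] == merged[-1][2]:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        runs = merged
    return [tuple(r) for r in runs]


def region_coverage(
    component: CoverageTrack,
    segments: ReplicationSegments,
    label: str,
) -> pd.DataFrame:
    """Summed CPM of one Repli-seq component (E or L) in every segment with
    the given label. Segments are typically computed on the untreated
    condition and reused across treatments so coverage is compared within
    fixed regions."""
    rows = []
    for chrom, segs in segments.segments.items():
        for s, e, lab in segs:
            if lab != label:
                continue
            rows.append({
                "chrom": chrom, "start": s, "end": e, "label": lab,
                "cpm": component.region_sum_cpm(chrom, s, e),
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "cpm"])


def distance_to_boundary(
    gene: GeneModel,
    segments: ReplicationSegments,
    from_label: str = "early",
    to_label: str = "late",
) -> float | None:
    """bp from the TES, in the direction of transcription, to the first
    boundary where the segment label switches from ``from_label`` to
    ``to_label``. ``None`` (excluded, flagged) when the TES is not inside a
    ``from_label`` segment or no such boundary lies downstream."""
    segs = segments.segments.get(gene.chrom)
    if not segs:
        return None
    tes = gene.tes
    idx = next((i for i, (s, e, _) in enumerate(segs) if s <= tes < e), None)
    if idx is None or segs[idx][2] != from_label:
        return None
    if gene.strand == "+":
        for i in range(idx, len(segs) - 1):
            if segs[i][2] == from_label and segs[i + 1][2] == to_label:
                return float(segs[i][1] - tes)
    else:
        for i in range(idx, 0, -1):
            if segs[i][2] == from_label and segs[i - 1][2] == to_label:
                return float(tes - segs[i][0])
    return None


def readthrough_direction(
    gene: GeneModel, dog_length: int, segments: ReplicationSegments
) -> str:
    """Classify a DoG's trajectory through replication domains by the
    labels at its TES and at the far end of the called readthrough."""
    start_lab = segments.label_at(gene.chrom, gene.tes)
    end_pos = gene.tes + dog_length if gene.strand == "+" else gene.tes - dog_length
    chrom_end = max(e for _, e, _ in segments.segments[gene.chrom])
    end_pos = min(max(end_pos, 0), chrom_end - 1)
    end_lab = segments.label_at(gene.chrom, end_pos)
    if start_lab == end_lab:
        return f"within-{start_lab}"
    return f"{start_lab}→{end_lab}"


def peaks_in_late(
    peaks: list[tuple[str, int, int]], segments: ReplicationSegments
) -> tuple[int, int]:
    """Count peaks overlapping (>= 1 bp) late segments, and the total
    overlapping bp."""
    count, bp = 0, 0
    for chrom, ps, pe in peaks:
        ov = 0
        for s, e, lab in segments.segments.get(chrom, []):
            if lab == "late":
                ov += max(0, min(pe, e) - max(ps, s))
        if ov > 0:
            count += 1
            bp += ov
    return count, bp


def exclude_chromosomes(dataset, names: list[str]):
    """Drop records on the named chromosomes (e.g. a chromosome with copy-
    number variation that corrupts RT calling). Accepts a gene list, a
    DataFrame with a ``chrom`` column, or a per-chromosome dict."""
    names = set(names)
    if isinstance(dataset, pd.DataFrame):
        present = names & set(dataset["chrom"])
        _warn_missing(names - present)
        return dataset[~dataset["chrom"].isin(names)].reset_index(drop=True)
    if isinstance(dataset, dict):
        _warn_missing(names - set(dataset))
        return {k: v for k, v in dataset.items() if k not in names}
    present = names & {g.chrom for g in dataset}
    _warn_missing(names - present)
    return [g for g in dataset if g.chrom not in names]


def _warn_missing(missing: set[str]) -> None:
    if missing:
        warnings.warn(f"chromosomes not present: {sorted(missing)}", stacklevel=3)
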