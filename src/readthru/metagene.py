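"""Scaled metagene profiles, downstream-of-TES profiles, and the SLAM/NERD
elongation indices.

The SLAM index is the slope of an ordinary least-squares fit of T>C-labeled
(nascent) read signal across the scaled gene body from TSS to TES; the NERD
index is the same slope computed on nonexonic (intronic) reads. Elongation
inhibition shifts nascent signal 5', making the slope more negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CoverageTrack, GeneModel


@dataclass
class MetageneProfile:
    """Average signal over flanks and a length-normalized gene body.

    ``values`` concatenates upstream-flank bins (native resolution), body
    bins (each gene rescaled to ``n_body_bins``) and downstream-flank bins;
    oriented so the TSS is always on the left.
    """

    upstream_flank: int
    n_body_bins: int
    downstream_flank: int
    bin_size: int
    values: np.ndarray
    n_genes: int
    smoothed: np.ndarray | None = None

    @property
    def n_flank_bins(self) -> int:
        return self.upstream_flank // self.bin_size

    @property
    def body(self) -> np.ndarray:
        lo = self.n_flank_bins
        return self.values[lo: lo + self.n_body_bins]

    @property
    def body_positions(self) -> np.ndarray:
        """Scaled TSS->TES positions in [0, 1] for the body bins."""
        return np.linspace(0.0, 1.0, self.n_body_bins)


@dataclass
class ElongationIndex:
    slope: float
    intercept: float
    r2: float
    variant: str  # "SLAM" (T>C reads) or "NERD" (nonexonic reads)


def select_top_expressed(
    genes: list[GeneModel], expression: pd.Series | dict[str, float], k: int
) -> list[GeneModel]:
    """The k highest-expressed genes (reference-condition FPKM), ties broken
    by gene_id."""
    expr = dict(expression)
    missing = [g.gene_id for g in genes if g.gene_id not in expr]
    if missing:
        raise ValueError(f"expression undefined for genes: {missing[:5]}...")
    if k > len(genes):
        warnings.warn(f"k={k} exceeds gene count {len(genes)}; returning all genes",
                      stacklevel=2)
        k = len(genes)
    ranked = sorted(genes, key=lambda g: (-expr[g.gene_id], g.gene_id))
    return ranked[:k]


def select_longest_decile(genes: list[GeneModel]) -> list[GeneModel]:
    """The 10% longest genes (nearest-rank: exactly ceil(n/10) genes, ties
    broken by gene_id)."""
    n = len(genes)
    if n < 10:
        raise ValueError("need at least 10 genes for a longest-decile selection")
    m = -(-n // 10)
    ranked = sorted(genes, key=lambda g: (-g.length, g.gene_id))
    return ranked[:m]


def _gene_body_values(track: CoverageTrack, gene: GeneModel, n_body_bins: int) -> np.ndarray:
    """Rescale a gene's binned CPM to n_body_bins by linear interpolation of
    bin midpoints on the scaled [0, 1] axis, TSS on the left."""
    cpm = track.cpm(gene.chrom)
    bs = track.bin_size
    lo, hi = gene.start // bs, -(-gene.end // bs)
    vals = cpm[lo:hi]
    mids = (np.arange(lo, hi) + 0.5) * bs
    u = (mids - gene.start) / gene.length
    targets = np.linspace(0.0, 1.0, n_body_bins)
    body = np.interp(targets, u, vals)
    return body[::-1] if gene.strand == "-" else body


def _flank_values(track: CoverageTrack, gene: GeneModel, flank: int, side: str) -> np.ndarray:
    """Flank bins outside the gene at native resolution, oriented in the
    direction of transcription ('up' ends at the TSS, 'down' starts at TES)."""
    cpm = track.cpm(gene.chrom)
    bs = track.bin_size
    nb = flank // bs
    if gene.strand == "+":
        start = gene.start - flank if side == "up" else gene.end
    else:
        start = gene.end if side == "up" else gene.start - flank
    idx = start // bs + np.arange(nb)
    vals = np.where((idx >= 0) & (idx < len(cpm)), cpm[np.clip(idx, 0, len(cpm) - 1)], 0.0)
    return vals[::-1] if gene.strand == "-" else vals


def metagene_profile(
    track: CoverageTrack,
    genes: list[GeneModel],
    n_body_bins: int = 100,
    flank: int = 5_000,
    outlier_factor: float = 50.0,
    smooth: bool = False,
    smooth_span: float = 0.1,
) -> MetageneProfile:
    """Average CPM profile over flanks and length-normalized gene bodies.

    Genes whose maximum body bin exceeds ``outlier_factor`` times the
    cross-gene median bin value are excluded (local read pileups would
    otherwise dominate the mean). Optional smoothing (local linear
    regression, for presentation only) is stored separately and never feeds
    the elongation index.
    """
    genes = [g for g in genes if g.length > 2 * track.bin_size]
    if not genes:
        raise ValueError("no genes long enough to profile")
    bodies = np.array([_gene_body_values(track, g, n_body_bins) for g in genes])
    ups = np.array([_flank_values(track, g, flank, "up") for g in genes])
    downs = np.array([_flank_values(track, g, flank, "down") for g in genes])
    med = np.median(bodies)
    if med > 0 and outlier_factor is not None:
        keep = bodies.max(axis=1) <= outlier_factor * med
        if keep.sum() == 0:
            keep[:] = True
        bodies, ups, downs = bodies[keep], ups[keep], downs[keep]
    values = np.concatenate([ups.mean(axis=0), bodies.mean(axis=0), downs.mean(axis=0)])
    smoothed = None
    if smooth:
        from statsmodels.nonparametric.smoothers_lowess import lowess
        x = np.arange(len(values), dtype=float)
        smoothed = lowess(values, x, frac=smooth_span, return_sorted=False)
    return MetageneProfile(
        upstream_flank=flank, n_body_bins=n_body_bins, downstream_flank=flank,
        bin_size=track.bin_size, values=values, n_genes=len(bodies), smoothed=smoothed,
    )


def elongation_index(profile: MetageneProfile, variant: str = "NERD") -> ElongationIndex:
    """OLS slope of body signal on scaled TSS->TES position in [0, 1].

    A more negative slope means stronger 5' accumulation / 3' depletion,
    i.e. a stronger elongation defect. Constant profiles give slope 0 with
    r^2 = 0.
    """
    y = profile.body
    if len(y) < 3:
        raise ValueError("need at least 3 body bins")
    x = profile.body_positions
    if np.ptp(y) == 0:
        return ElongationIndex(0.0, float(y[0]), 0.0, variant)
    fit = stats.linregress(x, y)
    return ElongationIndex(float(fit.slope), float(fit.intercept),
                           float(fit.rvalue ** 2), variant)


def downstream_profile(
    track: CoverageTrack,
    genes: list[GeneModel],
    extent: int = 100_000,
    window: int = 5_000,
) -> pd.DataFrame:
    """Windowed CPM past the TES, strand-aware.

    Windows are indexed from the TES outward in the direction of
    transcription; each value is the total CPM attributed to the window.
    Windows running past a chromosome end are NaN (flagged truncated).
    Returns a genes x windows DataFrame; the column mean is the average
    downstream profile.
    """
    if extent % window:
        raise ValueError("extent must be a multiple of window")
    n_win = extent // window
    rows = {}
    for g in genes:
        chrom_len = len(track.counts[g.chrom]) * track.bin_size
        vals = np.empty(n_win)
        for w in range(n_win):
            s, e = g.downstream_interval(w * window, window)
            if s < 0 or e > chrom_len:
                vals[w] = np.nan
            else:
                vals[w] = track.region_sum_cpm(g.chrom, s, e)
        rows[g.gene_id] = vals
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"w{w + 1}" for w in range(n_win)])
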