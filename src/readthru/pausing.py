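"""RNAPII pausing index and length-dependent expression fold change.

The pausing index is the ratio of RNAPII read density in a promoter-
proximal TSS window to the average density over the gene body; high values
indicate promoter-proximal pausing. Isoform selection follows the rule:
among isoforms longer than 1 kb with nonzero average signal at both TSS
and body, take the one with the highest TSS signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CoverageTrack, GeneModel

TSS_WINDOW = (50, 300)  # bp upstream, downstream of the TSS


@dataclass
class PausingIndex:
    gene_id: str
    isoform_id: str
    tss_density: float   # CPM per bp over the TSS window
    body_density: float  # CPM per bp over the gene body
    index: float


def _tss_interval(g: GeneModel, up: int, down: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.tss - up, g.tss + down
    return g.tss - down + 1, g.tss + up + 1


def _body_interval(g: GeneModel, down: int) -> tuple[int, int]:
    """Gene body: from the downstream edge of the TSS window to the TES."""
    if g.strand == "+":
        return g.tss + down, g.end
    return g.start, g.tss - down + 1


def select_pausing_isoform(
    isoforms: list[GeneModel],
    coverage: CoverageTrack,
    tss_window: tuple[int, int] = TSS_WINDOW,
    min_length: int = 1_000,
) -> GeneModel | None:
    """Pick the isoform to score: length > ``min_length`` bp, average signal
    > 0 at both TSS window and body, highest TSS signal wins."""
    up, down = tss_window
    best, best_sig = None, -np.inf
    for iso in isoforms:
        if iso.length <= min_length:
            continue
        ts, te = _tss_interval(iso, up, down)
        bs_, be = _body_interval(iso, down)
        if be <= bs_ or ts < 0:
            continue
        tss_d = coverage.region_density(iso.chrom, ts, te)
        body_d = coverage.region_density(iso.chrom, bs_, be)
        if tss_d <= 0 or body_d <= 0:
            continue
        if tss_d > best_sig or (tss_d == best_sig and best is not None
                                and iso.isoform_id < best.isoform_id):
            best, best_sig = iso, tss_d
    return best


def pausing_index(
    isoform: GeneModel,
    coverage: CoverageTrack,
    tss_window: tuple[int, int] = TSS_WINDOW,
) -> PausingIndex | None:
    """TSS-window density over gene-body density, both in CPM/bp.

    Library size cancels in the ratio, so the index is invariant to depth.
    Returns ``None`` (excluded, never zero-filled) when the body density is
    zero or the body is empty.
    """
    up, down = tss_window
    ts, te = _tss_interval(isoform, up, down)
    bs_, be = _body_interval(isoform, down)
    if be <= bs_:
        return None
    tss_d = coverage.region_density(isoform.chrom, max(ts, 0), te)
    body_d = coverage.region_density(isoform.chrom, bs_, be)
    if body_d == 0:
        return None
    return PausingIndex(
        gene_id=isoform.gene_id, isoform_id=isoform.isoform_id,
        tss_density=tss_d, body_density=body_d, index=tss_d / body_d,
    )


def pausing_table(
    genes: list[GeneModel],
    coverage: CoverageTrack,
    tss_window: tuple[int, int] = TSS_WINDOW,
) -> pd.DataFrame:
    """Pausing index for every gene with a qualifying isoform."""
    by_gene: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_gene.setdefault(g.gene_id, []).append(g)
    rows = []
    for gid in sorted(by_gene):
        iso = select_pausing_isoform(by_gene[gid], coverage, tss_window)
        if iso is None:
            continue
        pi = pausing_index(iso, coverage, tss_window)
        if pi is not None:
            rows.append(vars(pi))
    return pd.DataFrame(rows, columns=["gene_id", "isoform_id", "tss_density",
                                       "body_density", "index"])


def moving_average_fc(
    treated: pd.Series,
    control: pd.Series,
    lengths: pd.Series,
    window: int = 250,
    min_expression: float = 1.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Moving average of log2 fold change after ordering genes by length.

    ``treated`` and ``control`` are per-gene expression (CPM), indexed by
    gene id; genes below ``min_expression`` in both conditions are excluded
    before the log2 ratio (with pseudocount) is computed. The moving
    average covers ``window`` genes below and above each rank, shrinking at
    the ends; a window larger than the gene count degrades to the global
    mean with a warning.
    """
    common = treated.index.intersection(control.index).intersection(lengths.index)
    t, c, ln = treated[common], control[common], lengths[common]
    keep = (t >= min_expression) | (c >= min_expression)
    t, c, ln = t[keep], c[keep], ln[keep]
    if len(t) == 0:
        raise ValueError("no genes pass the expression filter")
    if window >= len(t):
        warnings.warn(f"window {window} >= gene count {len(t)}; moving average "
                      "degrades to the global mean", stacklevel=2)
    fc = np.log2((t + pseudocount) / (c + pseudocount))
    df = pd.DataFrame({"gene_id": common[keep], "length": ln.to_numpy(),
                       "log2_fc": fc.to_numpy()})
    df = df.sort_values(["length", "gene_id"], kind="stable").reset_index(drop=True)
    df["log2_length"] = np.log2(df["length"])
    df["ma_log2_fc"] = (
        df["log2_fc"].rolling(2 * window + 1, center=True, min_periods=1).mean()
    )
    return df
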