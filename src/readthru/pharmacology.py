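"""Bliss-independence synergy scoring and the caliper tumor-volume formula.

Effects are growth inhibition, 1 - relative viability. Under Bliss
independence two drugs with single-agent effects d1 and d2 combine to
d1 + d2 - d1*d2; the delta reported here is predicted - observed, so
synergy (observed effect exceeding the independent prediction) is
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def bliss_predicted_effect(d1: float, d2: float) -> float:
    """Predicted combined effect of independent drugs: d1 + d2 - d1*d2."""
    for d in (d1, d2):
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"effects must be in [0, 1], got {d}")
    return d1 + d2 - d1 * d2


@dataclass
class Checkerboard:
    """Dose-matrix viability data.

    ``viability[i, j]`` is the fraction of untreated-control viability at
    ``doses1[i]`` of drug 1 and ``doses2[j]`` of drug 2. Both dose grids
    must include 0 so single-agent effects are available, and viability at
    (0, 0) must be 1 (the normalization anchor).
    """

    doses1: np.ndarray
    doses2: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.doses1 = np.asarray(self.doses1, dtype=float)
        self.doses2 = np.asarray(self.doses2, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape != (len(self.doses1), len(self.doses2)):
            raise ValueError("viability matrix shape must match dose grids")
        if 0.0 not in self.doses1 or 0.0 not in self.doses2:
            raise ValueError("dose grids must include 0 (single-agent rows/columns)")
        i0, j0 = self._zero_idx()
        if not math.isclose(self.viability[i0, j0], 1.0, abs_tol=1e-9):
            raise ValueError("viability must be normalized to 1 at dose (0, 0)")

    def _zero_idx(self) -> tuple[int, int]:
        return int(np.where(self.doses1 == 0)[0][0]), int(np.where(self.doses2 == 0)[0][0])

    @property
    def effect(self) -> np.ndarray:
        return 1.0 - self.viability

    @classmethod
    def from_tsv(cls, path) -> "Checkerboard":
        """Read a plate layout: first column drug-1 doses, header row drug-2
        doses, body viability fractions."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.index.to_numpy(float), df.columns.to_numpy(float), df.to_numpy(float))


def delta_bliss(cb: Checkerboard) -> np.ndarray:
    """Delta-Bliss matrix: predicted minus observed effect per well.

    More negative values mean stronger synergy; single-agent rows/columns
    come out 0 by construction. Effects outside [0, 1] (assay noise pushing
    viability above control) are clipped for the prediction only.
    """
    eff = cb.effect
    i0, j0 = cb._zero_idx()
    d1 = np.clip(eff[:, j0], 0.0, 1.0)
    d2 = np.clip(eff[i0, :], 0.0, 1.0)
    predicted = d1[:, None] + d2[None, :] - d1[:, None] * d2[None, :]
    return predicted - eff


def tumor_volume(major_mm: float, minor_mm: float) -> float:
    """Caliper tumor volume in mm^3: (pi/6) * D * d^2 with D the major and
    d the minor axis."""
    if minor_mm <= 0:
        raise ValueError("axes must be positive")
    if minor_mm > major_mm:
        raise ValueError("minor axis exceeds major axis (swapped arguments?)")
    return (math.pi / 6.0) * major_mm * minor_mm ** 2
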