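"""Circular statistics and histograms over per-residue angles.

The circular mean of angles a_i is atan2(Σ sin a_i, Σ cos a_i); the mean
resultant length R = |Σ (cos, sin)| / n lies in [0, 1] and the circular
standard deviation is sqrt(−2 ln R) (Mardia), reported in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .torsion_core import AngleKind, ResidueTorsions, wrap_half

__all__ = ["CircularSummary", "AngleHistogram", "circular_mean", "histogram", "syn_anti_counts"]


@dataclass
class CircularSummary:
    n_defined: int
    mean: float  # degrees in (-180, 180]; NaN when undefined
    resultant_length: float
    circular_std: float  # degrees; NaN when undefined
    kind: Optional[AngleKind] = None


@dataclass
class AngleHistogram:
    bin_width: float
    lo: float  # start of the first bin (degrees)
    counts: np.ndarray  # integer counts, one per bin
    kind: Optional[AngleKind] = None

    @property
    def edges(self) -> np.ndarray:
        nbins = len(self.counts)
        return self.lo + self.bin_width * np.arange(nbins + 1)


def circular_mean(angles: Sequence[float], kind: Optional[AngleKind] = None) -> CircularSummary:
    """Circular mean / resultant length / circular std of ``angles`` (degrees).

    NaN entries are dropped.  With no defined value, or an (anti-)symmetric
    set whose resultant vanishes, the mean and std are NaN.
    """
    arr = np.asarray([a for a in angles if np.isfinite(a)], dtype=float)
    n = arr.size
    if n == 0:
        return CircularSummary(0, float("nan"), float("nan"), float("nan"), kind)
    rad = np.radians(arr)
    s, c = np.sin(rad).sum(), np.cos(rad).sum()
    r = float(math.hypot(s, c) / n)
    if r < 1e-12:
        return CircularSummary(n, float("nan"), 0.0, float("nan"), kind)
    mean = wrap_half(math.degrees(math.atan2(s, c)))
    std = math.degrees(math.sqrt(max(-2.0 * math.log(min(r, 1.0)), 0.0)))
    return CircularSummary(n, float(mean), r, std, kind)


def histogram(
    angles: Sequence[float],
    bin_width: float = 15.0,
    lo: float = -180.0,
    kind: Optional[AngleKind] = None,
) -> AngleHistogram:
    """Histogram with half-open bins [lo + k·w, lo + (k+1)·w) tiling 360°.

    Values are wrapped into [lo, lo + 360) first, so counts are conserved
    under any 360° re-representation of the input.
    """
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ConfigError(f"bin width {bin_width}° must evenly divide 360°")
    nbins = int(round(360.0 / bin_width))
    arr = np.asarray([a for a in angles if np.isfinite(a)], dtype=float)
    wrapped = (arr - lo) % 360.0
    idx = np.floor(wrapped / bin_width).astype(int)
    idx = np.clip(idx, 0, nbins - 1)  # guard against 360.0-epsilon rounding
    counts = np.bincount(idx, minlength=nbins) if arr.size else np.zeros(nbins, dtype=int)
    return AngleHistogram(bin_width=bin_width, lo=lo, counts=counts, kind=kind)


def syn_anti_counts(torsions: Sequence[ResidueTorsions]) -> dict[str, int]:
    """Tally of glycosidic-bond conformations over residues."""
    counts = {"syn": 0, "anti": 0, "undefined": 0}
    for t in torsions:
        counts[t.glycosidic] += 1
    return counts
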