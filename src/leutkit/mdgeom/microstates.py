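"""Gate time series and 2D collective-variable density maps.

Projecting every trajectory snapshot onto the (salt-bridge distance,
hydrogen-bond distance) plane and histogramming yields a density map whose
local maxima are the *microstates* of the intracellular gate; each is
labeled alphabetically by decreasing population and reported with a
representative frame.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .frame import MissingAtomError, MolecularFrame
from .gates import GateDefinition, chi1, gate_distances

__all__ = ["GateTimeSeries", "gate_time_series", "Microstate",
           "MicrostateMap", "cv_density"]


@dataclass
class GateTimeSeries:
    """Per-frame gate distances (Angstrom) and Y-residue chi1 (degrees;
    NaN where the dihedral atoms are absent)."""

    salt_bridge: np.ndarray
    hbond: np.ndarray
    chi1_deg: np.ndarray
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        n = self.salt_bridge.size
        if not (self.hbond.size == self.chi1_deg.size
                == self.frame_indices.size == n):
            raise ValueError("time-series columns must have equal length")
        if np.any(self.salt_bridge <= 0) or np.any(self.hbond <= 0):
            raise ValueError("gate distances must be positive")

    @property
    def n_frames(self) -> int:
        return self.salt_bridge.size


def gate_time_series(frames: Iterable[MolecularFrame],
                     gates: GateDefinition = GateDefinition(),
                     chain: Optional[str] = None) -> GateTimeSeries:
    """Evaluate both gate distances and chi1 over a frame sequence."""
    d1, d2, x1, idx = [], [], [], []
    for frame in frames:
        a, b = gate_distances(frame, gates, chain=chain)
        d1.append(a)
        d2.append(b)
        try:
            x1.append(chi1(frame, gates.chi1_residue, chain=chain))
        except MissingAtomError:
            x1.append(np.nan)
        idx.append(frame.frame_index)
    return GateTimeSeries(salt_bridge=np.asarray(d1), hbond=np.asarray(d2),
                          chi1_deg=np.asarray(x1),
                          frame_indices=np.asarray(idx, dtype=int))


@dataclass
class Microstate:
    label: str
    center: tuple[float, float]   # bin-center coordinates (Angstrom)
    count: int
    representative_frame: int     # frame index nearest the bin center


@dataclass
class MicrostateMap:
    """2D gate-distance histogram with ranked local density maxima."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    microstates: list[Microstate]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _edges(values: np.ndarray, bin_width: float,
           origin: Optional[float]) -> np.ndarray:
    lo = values.min() if origin is None else origin
    if origin is not None and lo > values.min():
        raise ValueError("histogram origin must not exceed the data minimum")
    n = max(1, int(np.ceil((values.max() - lo) / bin_width + 1e-12)))
    return lo + np.arange(n + 1) * bin_width


def cv_density(series: GateTimeSeries, bin_width: float = 0.25,
               n_peaks: int = 3,
               origin: Optional[tuple[float, float]] = None) -> MicrostateMap:
    """Histogram the (salt-bridge, hbond) projection and locate microstates.

    Microstates are the ``n_peaks`` most populated strict 8-neighborhood
    local maxima of the histogram (exact count ties across a plateau
    resolve to one peak, deterministically), labeled "a", "b", ... by
    decreasing count.  Histogram mass always equals the number of frames.
    """
    if series.n_frames < 100:
        warnings.warn("fewer than 100 frames: density map may be unreliable",
                      stacklevel=2)
    x, y = series.salt_bridge, series.hbond
    xe = _edges(x, bin_width, None if origin is None else origin[0])
    ye = _edges(y, bin_width, None if origin is None else origin[1])
    h, _, _ = np.histogram2d(x, y, bins=(xe, ye))

    padded = np.full((h.shape[0] + 2, h.shape[1] + 2), -1.0)
    padded[1:-1, 1:-1] = h
    peak = np.ones_like(h, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            neigh = padded[1 + di:padded.shape[0] - 1 + di,
                           1 + dj:padded.shape[1] - 1 + dj]
            if (di, dj) > (0, 0):
                # exact count ties across a plateau resolve to the bin that
                # comes first in scan order, so one peak per plateau
                peak &= h >= neigh
            else:
                peak &= h > neigh
    peak &= h > 0

    ii, jj = np.nonzero(peak)
    order = np.argsort(h[ii, jj])[::-1][:n_peaks]
    states = []
    for rank, k in enumerate(order):
        i, j = ii[k], jj[k]
        cx = 0.5 * (xe[i] + xe[i + 1])
        cy = 0.5 * (ye[j] + ye[j + 1])
        nearest = int(np.argmin((x - cx) ** 2 + (y - cy) ** 2))
        states.append(Microstate(
            label=string.ascii_lowercase[rank], center=(float(cx), float(cy)),
            count=int(h[i, j]),
            representative_frame=int(series.frame_indices[nearest])))
    return MicrostateMap(x_edges=xe, y_edges=ye, counts=h, microstates=states)
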