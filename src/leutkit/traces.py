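"""Per-molecule fluorescence and FRET trace containers.

A :class:`FluorescenceTrace` holds the raw (or bleed-through corrected)
donor/acceptor intensities of a single surface-immobilized molecule; a
:class:`FretTrace` holds the derived FRET efficiency together with the
photophysical dark-frame mask.  Both are thin, validated wrappers around
NumPy arrays so that downstream stages (selection, idealization, kinetics)
can operate vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["FluorescenceTrace", "FretTrace"]


@dataclass
class FluorescenceTrace:
    """Donor and (raw or corrected) acceptor intensity per frame.

    Parameters
    ----------
    donor, acceptor :
        Per-frame intensities in arbitrary (camera) units, equal length.
    frame_period :
        Integration time per frame in seconds (> 0).
    molecule_id :
        Identifier of the molecule within its recording.
    condition :
        Free-form condition label, e.g. a ligand name.
    concentration :
        Optional ligand concentration in molar, if the condition is a
        titration point.
    acceptor_is_corrected :
        Whether the acceptor channel has already had donor bleed-through
        subtracted.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    frame_period: float = 0.025
    molecule_id: str = "0"
    condition: str = ""
    concentration: Optional[float] = None
    acceptor_is_corrected: bool = False

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.acceptor.ndim != 1:
            raise ValueError("intensity channels must be 1-D arrays")
        if self.donor.shape != self.acceptor.shape:
            raise ValueError(
                f"channel length mismatch: donor has {self.donor.size} frames, "
                f"acceptor has {self.acceptor.size}"
            )
        if not self.frame_period > 0:
            raise ValueError("frame_period must be positive")

    def __len__(self) -> int:
        return self.donor.size

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        """Total intensity (donor + acceptor) per frame."""
        return self.donor + self.acceptor

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_frames * self.frame_period

    def with_channels(self, donor: np.ndarray, acceptor: np.ndarray,
                      corrected: Optional[bool] = None) -> "FluorescenceTrace":
        out = replace(self, donor=np.asarray(donor, float),
                      acceptor=np.asarray(acceptor, float))
        if corrected is not None:
            out.acceptor_is_corrected = corrected
        return out


@dataclass
class FretTrace:
    """FRET efficiency per frame with a dark-state mask.

    ``efficiency`` is E = I_A / (I_A + I_D) on live frames and exactly 0 on
    dark frames (donor blinked or photobleached).  Noise may push live-frame
    values slightly outside [0, 1].
    """

    efficiency: np.ndarray
    dark: np.ndarray
    frame_period: float = 0.025
    molecule_id: str = "0"
    condition: str = ""
    concentration: Optional[float] = None
    bleach_frame: Optional[int] = None

    def __post_init__(self) -> None:
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        self.dark = np.asarray(self.dark, dtype=bool)
        if self.efficiency.shape != self.dark.shape:
            raise ValueError("efficiency and dark mask must have equal length")
        if np.any(self.efficiency[self.dark] != 0.0):
            raise ValueError("efficiency must be exactly 0 on dark frames")
        if self.bleach_frame is not None and not (
                0 <= self.bleach_frame <= self.efficiency.size):
            raise ValueError("bleach_frame outside trace")

    def __len__(self) -> int:
        return self.efficiency.size

    @property
    def n_frames(self) -> int:
        return self.efficiency.size

    @property
    def live(self) -> np.ndarray:
        """Boolean mask of non-dark frames."""
        return ~self.dark
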