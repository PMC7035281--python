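"""Channel correction and FRET efficiency computation."""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..traces import FluorescenceTrace, FretTrace

__all__ = ["correct_bleed_through", "compute_fret"]

#: Fraction of donor emission detected in the raw acceptor channel.
DEFAULT_BLEED_THROUGH = 0.165


def correct_bleed_through(trace: FluorescenceTrace,
                          fraction: float = DEFAULT_BLEED_THROUGH
                          ) -> FluorescenceTrace:
    """Subtract the set fraction of donor intensity from the acceptor
    channel; the donor channel is unchanged."""
    if not 0 <= fraction < 1:
        raise ValueError("bleed-through fraction must lie in [0, 1)")
    corrected = trace.acceptor - fraction * trace.donor
    return trace.with_channels(trace.donor, corrected, corrected=True)


def compute_fret(trace: FluorescenceTrace,
                 dark_mask: Optional[np.ndarray] = None,
                 bleach_frame: Optional[int] = None) -> FretTrace:
    """FRET efficiency E = I_A / (I_A + I_D) per frame.

    Frames in ``dark_mask`` (donor dark: blinks, post-bleach) are set to
    exactly 0, as are frames whose total intensity is non-positive (pure
    background noise).
    """
    if not trace.acceptor_is_corrected:
        raise ValueError("correct bleed-through before computing FRET")
    total = trace.donor + trace.acceptor
    dark = np.zeros(trace.n_frames, dtype=bool)
    if dark_mask is not None:
        dark_mask = np.asarray(dark_mask, dtype=bool)
        if dark_mask.shape != (trace.n_frames,):
            raise ValueError("dark mask length must match the trace")
        dark |= dark_mask
    if bleach_frame is not None:
        dark[bleach_frame:] = True
    dark |= total <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(dark, 0.0, trace.acceptor / np.where(total == 0, 1.0,
                                                            total))
    return FretTrace(efficiency=eff, dark=dark,
                     frame_period=trace.frame_period,
                     molecule_id=trace.molecule_id, condition=trace.condition,
                     concentration=trace.concentration,
                     bleach_frame=bleach_frame)
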