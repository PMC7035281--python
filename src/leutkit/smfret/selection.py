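"""Photobleaching/blinking detection and trace selection.

A usable single-molecule trace shows a single irreversible drop of total
intensity to the background level (donor photobleaching), at most a few
reversible dark excursions before it (donor blinking), and adequate
signal-to-noise.  Traces are kept for kinetic analysis only if all five
criteria pass: (i) single-step donor photobleaching, (ii) SNR against the
background >= 8, (iii) SNR of the bleach step >= 5, (iv) fewer than four
blink events, and (v) FRET efficiency above 0.15 for at least 300 frames.

The two SNR figures are defined here as: SNR_background = mean pre-bleach
total intensity / SD of the post-bleach background, and SNR_signal =
bleach step amplitude / SD of the pre-bleach total intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..traces import FluorescenceTrace, FretTrace
from .correction import DEFAULT_BLEED_THROUGH, compute_fret, correct_bleed_through

__all__ = ["SelectionCriteria", "PhotophysicsReport",
           "detect_bleach_and_blinks", "select_traces"]


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the five selection criteria."""

    require_single_step_bleach: bool = True
    snr_background_min: float = 8.0
    snr_signal_min: float = 5.0
    max_blink_events: int = 3          # "fewer than four"
    min_frames: int = 300
    fret_floor: float = 0.15

    def __post_init__(self) -> None:
        if min(self.snr_background_min, self.snr_signal_min,
               self.max_blink_events, self.min_frames, self.fret_floor) < 0:
            raise ValueError("selection thresholds must be non-negative")


@dataclass
class PhotophysicsReport:
    """Detected photophysics of one trace."""

    bleach_frame: Optional[int]
    single_step: bool
    blink_intervals: list[tuple[int, int]]   # [start, end) frame ranges
    snr_background: float
    snr_signal: float
    on_mask: np.ndarray

    @property
    def n_blinks(self) -> int:
        return len(self.blink_intervals)

    def dark_mask(self) -> np.ndarray:
        dark = ~self.on_mask
        if self.bleach_frame is not None:
            dark[self.bleach_frame:] = True
        return dark


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate(
        [[0], mask.astype(int), [0]])))
    return list(zip(idx[0::2].tolist(), idx[1::2].tolist()))


def _despeckle(mask: np.ndarray) -> np.ndarray:
    """Remove isolated single-frame flips (3-point majority vote)."""
    if mask.size < 3:
        return mask
    out = mask.copy()
    tri = mask[:-2].astype(int) + mask[1:-1] + mask[2:]
    out[1:-1] = tri >= 2
    return out


def _best_internal_step(values: np.ndarray) -> float:
    """Largest mean shift over all internal split points of a sequence."""
    n = values.size
    if n < 4:
        return 0.0
    cum = np.cumsum(values)
    k = np.arange(2, n - 1)
    left = cum[k - 1] / k
    right = (cum[-1] - cum[k - 1]) / (n - k)
    return float(np.max(np.abs(left - right)))


def detect_bleach_and_blinks(trace: FluorescenceTrace) -> PhotophysicsReport:
    """Locate the photobleach, blink intervals and SNR figures of a trace.

    The bleach is the start of the trailing dark run of total intensity; a
    trace that never drops to background has ``bleach_frame = None`` (and
    will fail the single-step criterion).
    """
    if trace.n_frames < 10:
        raise ValueError("at least 10 frames are required")
    total = trace.total
    n = total.size

    # background level anchored at the trace tail; signal amplitude from a
    # high quantile so early bleaches are still seen
    tail = total[-max(3, n // 50):]
    bg0 = float(np.median(tail))
    amp = float(np.percentile(total, 99)) - bg0
    noise = 1.4826 * float(np.median(np.abs(np.diff(total)))) / np.sqrt(2)
    bleach: Optional[int] = None
    on = np.zeros(n, dtype=bool)
    bg_mean = bg_sd = np.nan
    if amp > max(5.0 * noise, 1e-9):
        on = _despeckle(total > bg0 + 0.3 * amp)
        if on.any() and not on[-1]:
            bleach = int(_runs(on)[-1][1])
        if bleach is not None:
            bg = total[bleach:]
            bg_mean = float(bg.mean())
            bg_sd = float(bg.std(ddof=1)) if bg.size > 1 else np.nan
            # refine the on/off threshold against the measured background
            pre_on = total[:bleach][on[:bleach]]
            if pre_on.size:
                theta = bg_mean + 0.3 * (float(pre_on.mean()) - bg_mean)
                on = _despeckle(total > theta)
                if on.any() and not on[-1]:
                    bleach = int(_runs(on)[-1][1])
                else:
                    bleach = None

    if bleach is None:
        return PhotophysicsReport(None, False, [], np.nan, np.nan, on)

    pre_on_mask = on.copy()
    pre_on_mask[bleach:] = False
    pre_on = total[pre_on_mask]
    pre_mean = float(pre_on.mean()) if pre_on.size else np.nan
    pre_sd = float(pre_on.std(ddof=1)) if pre_on.size > 1 else np.nan
    step = pre_mean - bg_mean

    snr_background = pre_mean / bg_sd if bg_sd and bg_sd > 0 else np.inf
    snr_signal = step / pre_sd if pre_sd and pre_sd > 0 else np.inf

    blinks = [(a, b) for a, b in _runs(~on[:bleach])]

    # single step: the on-level before the bleach must hold one plateau
    single = True
    if pre_on.size >= 4:
        sigma = 1.4826 * float(np.median(np.abs(np.diff(pre_on)))) / np.sqrt(2)
        internal = _best_internal_step(pre_on)
        single = internal <= max(4.0 * sigma, 0.3 * abs(step))
    return PhotophysicsReport(bleach_frame=bleach, single_step=single,
                              blink_intervals=blinks,
                              snr_background=float(snr_background),
                              snr_signal=float(snr_signal), on_mask=on)


def select_traces(traces: Sequence[FluorescenceTrace],
                  criteria: SelectionCriteria = SelectionCriteria(),
                  bleed_fraction: float = DEFAULT_BLEED_THROUGH
                  ) -> tuple[list[FretTrace], pd.DataFrame]:
    """Run correction, photophysics detection and the five-criterion filter.

    Returns the accepted FRET traces and a per-trace report with one boolean
    column per criterion.
    """
    rows = []
    accepted: list[FretTrace] = []
    for trace in traces:
        corr = (trace if trace.acceptor_is_corrected
                else correct_bleed_through(trace, bleed_fraction))
        rep = detect_bleach_and_blinks(corr)
        fret = compute_fret(corr, dark_mask=rep.dark_mask(),
                            bleach_frame=rep.bleach_frame)
        n_above = int(np.sum(fret.efficiency > criteria.fret_floor))
        checks = {
            "single_step_bleach": (rep.bleach_frame is not None
                                   and rep.single_step)
            if criteria.require_single_step_bleach else True,
            "snr_background_ok":
                rep.snr_background >= criteria.snr_background_min,
            "snr_signal_ok": rep.snr_signal >= criteria.snr_signal_min,
            "blinks_ok": rep.n_blinks <= criteria.max_blink_events,
            "fret_frames_ok": n_above >= criteria.min_frames,
        }
        ok = all(checks.values())
        rows.append({"molecule_id": trace.molecule_id, **checks,
                     "snr_background": rep.snr_background,
                     "snr_signal": rep.snr_signal,
                     "n_blinks": rep.n_blinks,
                     "n_frames_above_floor": n_above,
                     "bleach_frame": rep.bleach_frame, "accepted": ok})
        if ok:
            accepted.append(fret)
    return accepted, pd.DataFrame(rows)
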