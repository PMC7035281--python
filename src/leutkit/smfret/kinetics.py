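"""Dwell-based kinetics: transition density plots, rate constants and
state occupancies.

Transition-rate constants are estimated by the dwell-time maximum
likelihood estimator k_ij = N_ij / T_i (observed i->j transitions divided
by total time spent in i), with SE = sqrt(N_ij) / T_i.  Dwells shorter
than two frame periods are retained, but every rate table carries a
dead-time caveat: events faster than the camera integration time are
systematically missed, so rates approaching the frame rate are lower
bounds.

The zero-FRET state is photophysical, not conformational; by default its
frames and dwells are excluded from occupancy denominators and dwell
statistics, and transitions into or out of it are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..traces import FretTrace
from .skm import Dwell, IdealizedPath

__all__ = ["TransitionDensity", "transition_density", "RateEstimate",
           "estimate_rates", "occupancy", "OccupancyTable"]

DEAD_TIME_CAVEAT = ("dwells shorter than the camera integration time are "
                    "systematically missed; rates comparable to the frame "
                    "rate are underestimates")


def _dwell_means(path: IdealizedPath, fret: FretTrace) -> list[float]:
    return [float(np.mean(fret.efficiency[d.start:d.start + d.length]))
            for d in path.dwells]


@dataclass
class TransitionDensity:
    """2D histogram of (mean FRET before, mean FRET after) each transition."""

    edges: np.ndarray
    counts: np.ndarray              # counts[i, j]: before-bin i, after-bin j
    total_transitions: int
    observation_time: float         # seconds of selected (non-dark) data

    @property
    def transitions_per_second(self) -> float:
        if self.observation_time <= 0:
            return np.nan
        return self.total_transitions / self.observation_time


def transition_density(paths: Sequence[IdealizedPath],
                       frets: Sequence[FretTrace],
                       bin_width: float = 0.05,
                       exclude_states: tuple[int, ...] = (0,)
                       ) -> TransitionDensity:
    """Build the transition density plot of a set of idealized traces.

    Each dwell-to-dwell transition contributes one count at (mean observed
    FRET of the preceding dwell, mean observed FRET of the following
    dwell).  Transitions touching an excluded (dark) state are dropped and
    never bridged.
    """
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    n_bins = edges.size - 1
    counts = np.zeros((n_bins, n_bins))
    total = 0
    obs_time = 0.0
    for path, fret in zip(paths, frets):
        obs_time += float(np.sum(~fret.dark)) * fret.frame_period
        means = _dwell_means(path, fret)
        for d_prev, d_next, m_prev, m_next in zip(
                path.dwells[:-1], path.dwells[1:], means[:-1], means[1:]):
            if d_prev.state in exclude_states or d_next.state in exclude_states:
                continue
            i = min(int(np.clip(m_prev, 0, None) / bin_width), n_bins - 1)
            j = min(int(np.clip(m_next, 0, None) / bin_width), n_bins - 1)
            counts[i, j] += 1
            total += 1
    return TransitionDensity(edges=edges, counts=counts,
                             total_transitions=total,
                             observation_time=obs_time)


@dataclass
class RateEstimate:
    """Transition-rate matrix k_ij (s^-1) with SEs and sufficient stats.

    ``defined[i, j]`` is False where no time was observed in state i, in
    which case k_ij is NaN (undefined, not zero).  When a state shows no
    exits at all despite observed occupancy, its rates are zero and
    ``upper_bound_only[i]`` flags that only an upper bound is known.
    """

    k: np.ndarray
    se: np.ndarray
    n_transitions: np.ndarray
    occupancy_time: np.ndarray
    defined: np.ndarray
    upper_bound_only: np.ndarray
    caveat: str = DEAD_TIME_CAVEAT

    def relative_to(self, reference: "RateEstimate") -> np.ndarray:
        """Rates as fold change over a reference condition."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.k / reference.k


def estimate_rates(paths: Sequence[IdealizedPath],
                   frame_period: Optional[float] = None,
                   n_states: int = 4,
                   exclude_states: tuple[int, ...] = (0,),
                   dead_time: Optional[float] = None) -> RateEstimate:
    """Dwell-time MLE of the transition-rate matrix from idealized paths.

    Dwell runs in excluded states split the surrounding dwell sequence (no
    transition is counted across them).

    ``dead_time`` (seconds) enables a first-order missed-event correction:
    destination dwells shorter than the dead time escape detection, so the
    observed counts N_ij underestimate the true number of i->j transitions
    by the factor P(dwell_j >= tau) = exp(-lambda_j * tau).  The corrected
    rates solve k_ij = (N_ij / T_i) * exp(lambda_j * tau) with
    lambda_j = sum_m k_jm, by fixed-point iteration.  A natural choice is
    one frame period (the camera resolution).  The correction is first
    order only: it ignores dwell merging across missed events, which is
    quadratic in the missed fraction.
    """
    n_ij = np.zeros((n_states, n_states))
    t_i = np.zeros(n_states)
    for path in paths:
        dt = frame_period if frame_period is not None else path.frame_period
        for d in path.dwells:
            if d.state not in exclude_states:
                t_i[d.state] += d.length * dt
        for d_prev, d_next in zip(path.dwells[:-1], path.dwells[1:]):
            if d_prev.state in exclude_states or d_next.state in exclude_states:
                continue
            n_ij[d_prev.state, d_next.state] += 1
    defined = np.broadcast_to(t_i[:, None] > 0, (n_states, n_states)).copy()
    np.fill_diagonal(defined, False)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(defined, n_ij / t_i[:, None], np.nan)
        se = np.where(defined, np.sqrt(n_ij) / t_i[:, None], np.nan)
    np.fill_diagonal(k, 0.0)
    if dead_time is not None and dead_time > 0:
        boost = np.ones(n_states)
        for _ in range(50):
            lam = np.nansum(np.where(defined, k * boost[None, :], 0.0),
                            axis=1)
            new_boost = np.exp(np.clip(lam * dead_time, 0.0, 2.0))
            if np.allclose(new_boost, boost, rtol=1e-12):
                break
            boost = new_boost
        k = k * boost[None, :]
        se = se * boost[None, :]
    upper_bound = (t_i > 0) & (n_ij.sum(axis=1) == 0)
    return RateEstimate(k=k, se=se, n_transitions=n_ij, occupancy_time=t_i,
                        defined=defined, upper_bound_only=upper_bound)


@dataclass
class OccupancyTable:
    """Ensemble state occupancies (per condition) with SE over molecules."""

    states: np.ndarray              # reported (non-dark) state indices
    mean: np.ndarray                # ensemble mean occupancy per state
    se: np.ndarray                  # SE over molecules
    per_molecule: np.ndarray        # (n_molecules, n_states)
    n_molecules: int


def occupancy(paths: Sequence[IdealizedPath], n_states: int = 4,
              exclude_states: tuple[int, ...] = (0,)) -> OccupancyTable:
    """Fraction of non-excluded frames each molecule spends in each state,
    averaged over molecules with a standard error.

    Raises when every frame of every molecule is dark/excluded.
    """
    keep = [s for s in range(n_states) if s not in exclude_states]
    per_mol = []
    for path in paths:
        counts = np.bincount(path.states, minlength=n_states).astype(float)
        denom = counts[keep].sum()
        if denom > 0:
            per_mol.append(counts[keep] / denom)
    if not per_mol:
        raise ValueError("occupancy undefined: no non-dark frames observed")
    per_mol = np.asarray(per_mol)
    mean = per_mol.mean(axis=0)
    se = (per_mol.std(axis=0, ddof=1) / np.sqrt(per_mol.shape[0])
          if per_mol.shape[0] > 1 else np.zeros(len(keep)))
    return OccupancyTable(states=np.asarray(keep), mean=mean, se=se,
                          per_molecule=per_mol, n_molecules=per_mol.shape[0])
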