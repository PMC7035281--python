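"""Synthetic smFRET trace generator with attached ground truth.

The generator inverts the measurement model used by the analysis stages:
an exact (Gillespie) continuous-time Markov path over the conformational
states is binned into camera frames by *time averaging* the state FRET
means, converted to donor/acceptor photon counts, contaminated with donor
bleed-through into the acceptor channel, and finally degraded by Gaussian
camera noise, donor blinking and single-step photobleaching.  Because the
path is sampled in continuous time, dwells shorter than one frame produce
mixture-valued frames exactly as unresolved transitions do in real
recordings.

Ligand coupling: one transition pair (by default low -> intermediate FRET)
is modulated so that the forward rate is ``k_on * concentration`` and the
reverse rate is ``k_off``, which is the kinetic scheme behind the
dose-response analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ..traces import FluorescenceTrace
from .ctmc import (
    dominant_frame_states,
    frame_average,
    sample_path,
    stationary_distribution,
    validate_generator,
)

__all__ = [
    "LigandCoupling",
    "TraceSimConfig",
    "GroundTruth",
    "default_rate_matrix",
    "effective_rate_matrix",
    "simulate_traces",
    "simulate_titration",
    "derive_seed",
]

#: FRET efficiencies of the four-state emission model: a zero-FRET dark
#: state plus the inward-open (low), partially open (intermediate) and
#: occluded (high) conformations.
DEFAULT_STATE_MEANS = (0.0, 0.47, 0.63, 0.79)


def default_rate_matrix() -> np.ndarray:
    """Default conformational generator (s^-1) among the three non-zero
    states; the zero-FRET state is photophysical and kinetically inert.

    The low <-> intermediate exchange dominates; the intermediate <-> high
    exchange is slow and strongly favors the intermediate, so titrations of
    the coupled pair are nearly two-state.
    """
    q = np.zeros((4, 4))
    q[1, 2] = 1.0    # low -> intermediate
    q[2, 1] = 2.04   # intermediate -> low
    q[2, 3] = 0.05   # intermediate -> high
    q[3, 2] = 2.0    # high -> intermediate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@dataclass(frozen=True)
class LigandCoupling:
    """Concentration coupling of one transition pair.

    ``k_on`` is in M^-1 s^-1 (concentrations are carried in molar
    throughout), ``k_off`` in s^-1.  ``pair`` names the (from, to) state
    indices of the modulated forward transition.
    """

    k_on: float
    k_off: float
    pair: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("coupling rates must be non-negative")
        if self.pair[0] == self.pair[1]:
            raise ValueError("coupled pair must join two distinct states")


@dataclass
class TraceSimConfig:
    """Parameters of the trace generator; defaults are the imaging and
    emission-model conditions used throughout the analysis stages."""

    n_molecules: int = 100
    n_frames: int = 2000
    frame_period: float = 0.025
    state_means: tuple[float, ...] = DEFAULT_STATE_MEANS
    noise_sd: float = 0.06
    total_intensity: float = 1000.0
    bleed_through_fraction: float = 0.165
    bleach_rate: float = 0.0
    blink_rate: float = 0.0
    blink_recovery_rate: float = 1.0
    rate_matrix: Optional[np.ndarray] = None
    ligand_coupling: Optional[LigandCoupling] = None
    concentration: float = 0.0
    start_state: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.state_means, dtype=float)
        if means[0] != 0.0:
            raise ValueError("first state mean must be exactly 0 (dark state)")
        if np.any(np.diff(means) <= 0):
            raise ValueError("state_means must be strictly increasing")
        if self.rate_matrix is None:
            if means.size != 4:
                raise ValueError("a rate_matrix is required for non-4-state models")
            self.rate_matrix = default_rate_matrix()
        self.rate_matrix = validate_generator(self.rate_matrix)
        if self.rate_matrix.shape[0] != means.size:
            raise ValueError("rate_matrix size must match number of states")
        if not self.frame_period > 0:
            raise ValueError("frame_period must be positive")
        if not 0 <= self.bleed_through_fraction < 1:
            raise ValueError("bleed_through_fraction must lie in [0, 1)")
        if not self.total_intensity > 0:
            raise ValueError("total_intensity must be positive")
        if min(self.n_molecules, self.n_frames) < 1:
            raise ValueError("n_molecules and n_frames must be >= 1")
        if self.noise_sd < 0 or self.bleach_rate < 0 or self.blink_rate < 0:
            raise ValueError("noise and photophysics rates must be non-negative")
        if self.blink_rate > 0 and not self.blink_recovery_rate > 0:
            raise ValueError("blinking requires a positive recovery rate")

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_period

    @property
    def n_states(self) -> int:
        return len(self.state_means)


@dataclass
class GroundTruth:
    """Generating path and photophysics of one simulated molecule."""

    times: np.ndarray            # path breakpoints, times[0] == 0
    states: np.ndarray           # state on [times[i], times[i+1])
    bleach_time: float           # min(sampled bleach time, duration)
    bleached: bool               # whether bleaching occurred in-window
    blink_intervals: list[tuple[float, float]]
    molecule_id: str
    config: TraceSimConfig

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if self.bleach_time > self.config.duration + 1e-12:
            raise ValueError("bleach time exceeds trace duration")

    def frame_states(self) -> np.ndarray:
        """Dominant conformational state per frame (ignores photophysics)."""
        return dominant_frame_states(
            self.times, self.states, self.config.n_states,
            self.config.n_frames, self.config.frame_period)

    def dark_intervals(self) -> list[tuple[float, float]]:
        """Blink intervals plus the post-bleach tail, clipped to the trace."""
        out = [(a, min(b, self.bleach_time)) for a, b in self.blink_intervals
               if a < self.bleach_time]
        if self.bleached:
            out.append((self.bleach_time, self.config.duration))
        return out

    def frame_dark(self) -> np.ndarray:
        """Frames whose majority of integration time is donor-dark."""
        cfg = self.config
        edges = np.arange(cfg.n_frames + 1) * cfg.frame_period
        dark_time = np.zeros(cfg.n_frames)
        for a, b in self.dark_intervals():
            lo = np.clip(b, edges[:-1], edges[1:])
            hi = np.clip(a, edges[:-1], edges[1:])
            dark_time += lo - hi
        return dark_time > 0.5 * cfg.frame_period


def effective_rate_matrix(config: TraceSimConfig,
                          concentration: Optional[float] = None) -> np.ndarray:
    """Generator with the ligand-coupled pair set to (k_on*c, k_off)."""
    q = config.rate_matrix.copy()
    if config.ligand_coupling is not None:
        c = config.concentration if concentration is None else concentration
        if c < 0:
            raise ValueError("concentration must be non-negative")
        i, j = config.ligand_coupling.pair
        np.fill_diagonal(q, 0.0)
        q[i, j] = config.ligand_coupling.k_on * c
        q[j, i] = config.ligand_coupling.k_off
        np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _sample_blinks(rng: np.random.Generator, on_rate: float, off_rate: float,
                   t_end: float) -> list[tuple[float, float]]:
    """Alternating on/off telegraph process starting bright at t=0."""
    if on_rate <= 0:
        return []
    intervals = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / on_rate)
        if t >= t_end:
            break
        dark = rng.exponential(1.0 / off_rate)
        intervals.append((t, min(t + dark, t_end)))
        t += dark
        if t >= t_end:
            break
    return intervals


def _start_state(rng: np.random.Generator, config: TraceSimConfig,
                 q: np.ndarray) -> int:
    if config.start_state is not None:
        return int(config.start_state)
    pi = stationary_distribution(q)
    return int(rng.choice(pi.size, p=pi))


def simulate_one(rng: np.random.Generator, config: TraceSimConfig,
                 molecule_id: str) -> tuple[FluorescenceTrace, GroundTruth]:
    q = effective_rate_matrix(config)
    times, states = sample_path(rng, q, config.duration,
                                _start_state(rng, config, q))
    if config.bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / config.bleach_rate)
    else:
        t_bleach = np.inf
    bleached = t_bleach < config.duration
    blinks = _sample_blinks(rng, config.blink_rate, config.blink_recovery_rate,
                            min(t_bleach, config.duration))
    truth = GroundTruth(times=times, states=states,
                        bleach_time=min(t_bleach, config.duration),
                        bleached=bleached, blink_intervals=blinks,
                        molecule_id=molecule_id, config=config)

    means = np.asarray(config.state_means)
    e_frames = frame_average(times, states, means,
                             config.n_frames, config.frame_period)
    dark = truth.frame_dark()
    e_frames = np.where(dark, 0.0, e_frames)
    total = config.total_intensity
    live = (~dark).astype(float)
    i_d = total * (1.0 - e_frames) * live
    i_a_true = total * e_frames * live
    i_a_raw = i_a_true + config.bleed_through_fraction * i_d
    if config.noise_sd > 0:
        sigma = config.noise_sd * total
        i_d = i_d + rng.normal(0.0, sigma, size=i_d.shape)
        i_a_raw = i_a_raw + rng.normal(0.0, sigma, size=i_a_raw.shape)
    trace = FluorescenceTrace(
        donor=i_d, acceptor=i_a_raw, frame_period=config.frame_period,
        molecule_id=molecule_id, condition=config.condition_label(),
        concentration=(config.concentration
                       if config.ligand_coupling is not None else None),
        acceptor_is_corrected=False)
    return trace, truth


def _condition_label(config: TraceSimConfig) -> str:
    if config.ligand_coupling is not None:
        return f"{config.concentration:.6g} M"
    return "apo"


# attach as method without cluttering the dataclass definition
TraceSimConfig.condition_label = _condition_label  # type: ignore[attr-defined]


def simulate_traces(config: TraceSimConfig
                    ) -> tuple[list[FluorescenceTrace], list[GroundTruth]]:
    """Simulate ``config.n_molecules`` traces; identical config and seed
    give bitwise-identical output."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_molecules)
    traces, truths = [], []
    for m, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        trace, truth = simulate_one(rng, config, molecule_id=str(m))
        traces.append(trace)
        truths.append(truth)
    return traces, truths


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-condition sub-seed below 2**31."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
               % (2 ** 31))


def simulate_titration(config: TraceSimConfig, concentrations: Sequence[float]
                       ) -> dict[float, tuple[list[FluorescenceTrace],
                                              list[GroundTruth]]]:
    """Simulate one trace set per ligand concentration (molar).

    Only the coupled forward rate varies with concentration; per-condition
    seeds are derived deterministically from the master seed.
    """
    if config.ligand_coupling is None:
        raise ValueError("simulate_titration requires ligand_coupling")
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("empty concentration list")
    out = {}
    for i, c in enumerate(concentrations):
        sub = replace(config, concentration=float(c),
                      seed=derive_seed(config.seed, i))
        out[float(c)] = simulate_traces(sub)
    return out
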