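"""Continuous-time Markov chain primitives for the trace generator.

A conformational path is stored as ``(times, states)`` where ``times[0] == 0``
and state ``states[i]`` is occupied on ``[times[i], times[i+1])`` (the last
state until the end of the observation window).  Paths are sampled with the
exact Gillespie algorithm and only afterwards binned into camera frames, so
that dwells shorter than one frame produce the time-averaging artifact seen
in real recordings.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "validate_generator",
    "stationary_distribution",
    "sample_path",
    "frame_average",
    "frame_occupancy",
    "dominant_frame_states",
]


def validate_generator(rate_matrix: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Check that ``rate_matrix`` is a valid CTMC generator (rows sum to 0,
    non-negative off-diagonals) and return it as a float array."""
    q = np.asarray(rate_matrix, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("rate matrix must be square")
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be non-negative")
    if np.any(np.abs(q.sum(axis=1)) > atol * max(1.0, np.abs(q).max())):
        raise ValueError("generator rows must sum to zero")
    return q


def stationary_distribution(rate_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi @ Q = 0, restricted to the states
    reachable under the chain (unreachable states get weight 0)."""
    q = validate_generator(rate_matrix)
    n = q.shape[0]
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    active = (off.sum(axis=1) > 0) | (off.sum(axis=0) > 0)
    if not active.any():
        return np.full(n, 1.0 / n)
    sub = q[np.ix_(active, active)]
    scale = np.abs(sub).max()          # stationary vector is scale-invariant
    sub = sub / scale
    m = sub.shape[0]
    # Solve pi Q = 0 with sum(pi) = 1 via least squares.
    a = np.vstack([sub.T, np.ones(m)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pi_sub, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.zeros(n)
    pi[active] = np.clip(pi_sub, 0.0, None)
    return pi / pi.sum()


def sample_path(rng: np.random.Generator, rate_matrix: np.ndarray,
                t_max: float, start_state: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample an exact CTMC path on ``[0, t_max]`` starting in ``start_state``.

    Returns ``(times, states)`` with ``times[0] == 0`` and strictly
    increasing entries; absorbing states terminate the path early.
    """
    q = np.asarray(rate_matrix, dtype=float)
    exit_rates = -np.diag(q)
    times = [0.0]
    states = [int(start_state)]
    t = 0.0
    s = int(start_state)
    while True:
        lam = exit_rates[s]
        if lam <= 0:
            break
        t = t + rng.exponential(1.0 / lam)
        if t >= t_max:
            break
        probs = q[s].copy()
        probs[s] = 0.0
        probs = probs / lam
        s = int(rng.choice(probs.size, p=probs))
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=int)


def _cumulative_integral(times: np.ndarray, values: np.ndarray,
                         query: np.ndarray, t_max: float) -> np.ndarray:
    """Integral of the step function ``values[i]`` on ``[times[i], times[i+1])``
    evaluated at the (sorted) query points."""
    edges = np.append(times, t_max)
    seg = np.diff(edges)
    cum = np.concatenate([[0.0], np.cumsum(values * seg)])
    return np.interp(query, edges, cum)


def frame_average(times: np.ndarray, states: np.ndarray, state_values: np.ndarray,
                  n_frames: int, frame_period: float) -> np.ndarray:
    """Within-frame time-average of ``state_values[state(t)]``.

    Frames that contain a state jump take the duration-weighted mixture of
    the state values, reproducing how a camera integrates over unresolved
    transitions.
    """
    t_max = n_frames * frame_period
    edges = np.arange(n_frames + 1) * frame_period
    vals = np.asarray(state_values, dtype=float)[states]
    cum = _cumulative_integral(times, vals, edges, t_max)
    return np.diff(cum) / frame_period


def frame_occupancy(times: np.ndarray, states: np.ndarray, n_states: int,
                    n_frames: int, frame_period: float) -> np.ndarray:
    """Fraction of each frame spent in each state, shape (n_frames, n_states)."""
    t_max = n_frames * frame_period
    edges = np.arange(n_frames + 1) * frame_period
    occ = np.empty((n_frames, n_states))
    for k in range(n_states):
        indicator = (states == k).astype(float)
        cum = _cumulative_integral(times, indicator, edges, t_max)
        occ[:, k] = np.diff(cum) / frame_period
    return occ


def dominant_frame_states(times: np.ndarray, states: np.ndarray, n_states: int,
                          n_frames: int, frame_period: float) -> np.ndarray:
    """State occupying the largest share of each frame (ground-truth frame
    labels for recovery tests)."""
    return np.argmax(
        frame_occupancy(times, states, n_states, n_frames, frame_period), axis=1
    )
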