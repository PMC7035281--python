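"""Segmental K-means (SKM) trace idealization.

SKM alternates (a) a Viterbi assignment of every frame to one of the fixed
emission states under the current transition matrix and shared Gaussian
noise SD, and (b) re-estimation of the transition matrix and noise SD from
those assignments, until the assignment no longer changes.  The state FRET
means stay fixed throughout (they are part of the model, not fitted), which
makes idealizations comparable across conditions.

Likelihood ties in the Viterbi recursion are broken toward the lowest
state index, so idealization is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..traces import FretTrace

__all__ = ["StateModel", "Dwell", "IdealizedPath", "idealize_skm",
           "idealize_batch", "dwells_from_states"]

#: Emission means of the default 4-state model (zero-FRET dark state plus
#: the low / intermediate / high conformational states).
DEFAULT_MEANS = (0.0, 0.47, 0.63, 0.79)

_SIGMA_FLOOR = 1e-3        # keeps the noiseless case numerically exact
_TRANS_PSEUDOCOUNT = 1e-3  # avoids -inf log transition probabilities


@dataclass
class StateModel:
    """Fixed emission means + re-estimated transition matrix and noise SD."""

    means: tuple[float, ...] = DEFAULT_MEANS
    noise_sd: float = 0.06
    transition_matrix: Optional[np.ndarray] = None
    stay_probability: float = 0.95   # initial self-transition probability

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        if np.any(np.diff(means) <= 0):
            raise ValueError("state means must be sorted strictly ascending")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.transition_matrix is not None:
            a = np.asarray(self.transition_matrix, dtype=float)
            if a.shape != (means.size, means.size) or np.any(a < 0) or \
                    not np.allclose(a.sum(axis=1), 1.0):
                raise ValueError("transition matrix must be row-stochastic")

    @property
    def n_states(self) -> int:
        return len(self.means)

    def initial_transition_matrix(self) -> np.ndarray:
        n = self.n_states
        a = np.full((n, n), (1.0 - self.stay_probability) / (n - 1))
        np.fill_diagonal(a, self.stay_probability)
        return a


@dataclass(frozen=True)
class Dwell:
    state: int
    start: int      # first frame of the dwell
    length: int     # frames


@dataclass
class IdealizedPath:
    """Per-frame state assignment of one trace, plus its dwell list."""

    states: np.ndarray
    dwells: list[Dwell]
    log_likelihood: float
    converged: bool
    n_iterations: int
    frame_period: float
    noise_sd: float
    transition_matrix: np.ndarray
    molecule_id: str = "0"
    condition: str = ""
    concentration: Optional[float] = None

    @property
    def n_frames(self) -> int:
        return self.states.size


def dwells_from_states(states: np.ndarray) -> list[Dwell]:
    """Maximal runs of a constant state; dwells tile the trace exactly."""
    states = np.asarray(states)
    if states.size == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    return [Dwell(int(states[a]), int(a), int(b - a))
            for a, b in zip(starts, ends)]


def _viterbi(x: np.ndarray, means: np.ndarray, sigma: np.ndarray,
             log_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Viterbi decoding.

    x: (B, T) observations; sigma: (B,) shared noise SD per trace;
    log_a: (B, S, S) log transition matrices.  Returns (states (B, T),
    log-likelihood (B,)).  Ties resolve to the lowest state index.
    """
    b, t = x.shape
    s = means.size
    # emission log-likelihoods, (B, T, S)
    resid = x[:, :, None] - means[None, None, :]
    ll = -0.5 * (resid / sigma[:, None, None]) ** 2 \
        - np.log(sigma)[:, None, None] - 0.5 * np.log(2 * np.pi)
    delta = ll[:, 0, :] - np.log(s)            # uniform initial distribution
    back = np.empty((b, t, s), dtype=np.int16)
    back[:, 0, :] = 0
    for k in range(1, t):
        cand = delta[:, :, None] + log_a       # (B, S_prev, S_next)
        best = np.argmax(cand, axis=1)         # first max -> lowest index
        delta = np.take_along_axis(cand, best[:, None, :], axis=1)[:, 0, :] \
            + ll[:, k, :]
        back[:, k, :] = best
    states = np.empty((b, t), dtype=np.int16)
    states[:, -1] = np.argmax(delta, axis=1)
    loglik = np.max(delta, axis=1)
    for k in range(t - 1, 0, -1):
        states[:, k - 1] = np.take_along_axis(
            back[:, k, :], states[:, k, None].astype(int), axis=1)[:, 0]
    return states.astype(int), loglik


def _reestimate(x: np.ndarray, states: np.ndarray, n_states: int,
                means: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-trace transition matrix and shared noise SD from assignments."""
    b, t = x.shape
    counts = np.full((b, n_states, n_states), _TRANS_PSEUDOCOUNT)
    bi = np.repeat(np.arange(b), t - 1)
    np.add.at(counts, (bi, states[:, :-1].ravel(), states[:, 1:].ravel()), 1.0)
    a = counts / counts.sum(axis=2, keepdims=True)
    resid = x - means[states]
    sigma = np.sqrt(np.mean(resid ** 2, axis=1))
    return a, np.maximum(sigma, _SIGMA_FLOOR)


def idealize_batch(frets: Sequence[FretTrace],
                   model: StateModel = StateModel(),
                   max_iterations: int = 100) -> list[IdealizedPath]:
    """Idealize many traces; equal-length traces are decoded in one batch.

    Each trace keeps its own re-estimated transition matrix and noise SD
    (SKM is a per-trace algorithm); batching only vectorizes the work.
    """
    order = sorted(range(len(frets)), key=lambda i: frets[i].n_frames)
    out: list[Optional[IdealizedPath]] = [None] * len(frets)
    group: list[int] = []
    for i in order + [None]:                      # None flushes the last group
        if group and (i is None
                      or frets[i].n_frames != frets[group[0]].n_frames):
            paths = _skm_group([frets[j] for j in group], model,
                               max_iterations)
            for j, p in zip(group, paths):
                out[j] = p
            group = []
        if i is not None:
            group.append(i)
    return out  # type: ignore[return-value]


def _skm_group(frets: Sequence[FretTrace], model: StateModel,
               max_iterations: int) -> list[IdealizedPath]:
    means = np.asarray(model.means, dtype=float)
    n = means.size
    x = np.stack([f.efficiency for f in frets])
    if x.shape[1] < 2:
        raise ValueError("at least 2 frames are required for idealization")

    # initial assignment: nearest emission mean (lowest index on ties)
    states = np.argmin(np.abs(x[:, :, None] - means[None, None, :]), axis=2)
    if model.transition_matrix is not None:
        a = np.broadcast_to(model.transition_matrix,
                            (x.shape[0], n, n)).copy()
    else:
        a = np.broadcast_to(model.initial_transition_matrix(),
                            (x.shape[0], n, n)).copy()
    sigma = np.full(x.shape[0], max(model.noise_sd, _SIGMA_FLOOR))

    loglik = np.full(x.shape[0], -np.inf)
    converged = np.zeros(x.shape[0], dtype=bool)
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        new_states, loglik = _viterbi(x, means, sigma, np.log(a))
        converged = np.all(new_states == states, axis=1)
        states = new_states
        if converged.all():
            break
        a, sigma = _reestimate(x, states, n, means)
    # report parameters consistent with the final assignment
    a, sigma = _reestimate(x, states, n, means)

    paths = []
    for i, f in enumerate(frets):
        paths.append(IdealizedPath(
            states=states[i].copy(), dwells=dwells_from_states(states[i]),
            log_likelihood=float(loglik[i]), converged=bool(converged[i]),
            n_iterations=iterations, frame_period=f.frame_period,
            noise_sd=float(sigma[i]), transition_matrix=a[i].copy(),
            molecule_id=f.molecule_id, condition=f.condition,
            concentration=f.concentration))
    return paths


def idealize_skm(fret: FretTrace, model: StateModel = StateModel(),
                 max_iterations: int = 100) -> IdealizedPath:
    """Idealize a single trace (see :func:`idealize_batch`)."""
    return idealize_batch([fret], model, max_iterations)[0]
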