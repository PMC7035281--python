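"""Shared-EC50 dose-response fitting of ensemble state occupancies.

Each reported state's occupancy versus ligand concentration is modeled as

    occ_s(c) = base_s + amp_s * (c**h) / (c**h + EC50**h)

with one EC50 shared across all states and the Hill coefficient h fixed
(default 1.0): a single binding event drives all the occupancy changes, so
the curves must share their midpoint.  The fit is weighted least squares
with per-point SEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np

from .kinetics import OccupancyTable

__all__ = ["DoseResponseDataset", "DoseResponseFit", "fit_dose_response",
           "dose_response_from_titration"]


@dataclass
class DoseResponseDataset:
    """Per-concentration, per-state occupancy means and SEs.

    ``concentrations`` are molar; ``mean``/``se`` have shape
    (n_concentrations, n_states).
    """

    concentrations: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    state_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.mean = np.atleast_2d(np.asarray(self.mean, float))
        self.se = np.atleast_2d(np.asarray(self.se, float))
        if self.mean.shape != self.se.shape or \
                self.mean.shape[0] != self.concentrations.size:
            raise ValueError("mean/se must be (n_concentrations, n_states)")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any((self.mean < -1e-9) | (self.mean > 1 + 1e-9)):
            raise ValueError("occupancies must lie in [0, 1]")
        if not self.state_labels:
            self.state_labels = tuple(
                f"state{k}" for k in range(self.mean.shape[1]))

    @property
    def n_states(self) -> int:
        return self.mean.shape[1]


def dose_response_from_titration(
        occupancies: dict[float, OccupancyTable],
        state_labels: tuple[str, ...] = ("low", "intermediate", "high")
) -> DoseResponseDataset:
    """Assemble a dataset from per-concentration occupancy tables."""
    conc = np.array(sorted(occupancies))
    mean = np.stack([occupancies[c].mean for c in conc])
    se = np.stack([occupancies[c].se for c in conc])
    return DoseResponseDataset(concentrations=conc, mean=mean, se=se,
                               state_labels=state_labels)


@dataclass
class DoseResponseFit:
    ec50: float                 # molar
    ec50_se: float
    hill: float
    base: np.ndarray            # per state
    amp: np.ndarray             # per state
    identifiable: bool          # False when all amplitudes are ~0
    extrapolated: bool          # EC50 outside the tested range
    redchi: float
    state_labels: tuple[str, ...] = ()

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, float)[:, None]
        frac = conc ** self.hill / (conc ** self.hill + self.ec50 ** self.hill)
        return self.base[None, :] + self.amp[None, :] * frac


def fit_dose_response(dataset: DoseResponseDataset, hill: float = 1.0,
                      min_amplitude: float = 1e-3) -> DoseResponseFit:
    """Weighted shared-EC50 fit with the Hill coefficient fixed.

    Raises when fewer than 4 concentrations are available or when no state
    shows a resolvable amplitude (EC50 unidentifiable).
    """
    conc = dataset.concentrations
    if conc.size < 4:
        raise ValueError("at least 4 concentrations are required")
    mean, se = dataset.mean, dataset.se
    pos = conc[conc > 0]
    if pos.size == 0:
        raise ValueError("at least one positive concentration is required")
    weights = 1.0 / np.maximum(se, max(1e-6, 0.05 * np.nanmedian(
        se[se > 0]) if np.any(se > 0) else 1e-6))

    params = lmfit.Parameters()
    params.add("log10_ec50", value=float(np.log10(np.median(pos))),
               min=np.log10(pos.min()) - 6, max=np.log10(pos.max()) + 6)
    for s in range(dataset.n_states):
        params.add(f"base_{s}", value=float(mean[0, s]), min=-0.5, max=1.5)
        params.add(f"amp_{s}", value=float(mean[-1, s] - mean[0, s]),
                   min=-1.5, max=1.5)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        ec50 = 10.0 ** p["log10_ec50"].value
        frac = conc ** hill / (conc ** hill + ec50 ** hill)
        out = np.empty_like(mean)
        for s in range(dataset.n_states):
            model = p[f"base_{s}"].value + p[f"amp_{s}"].value * frac
            out[:, s] = (model - mean[:, s]) * weights[:, s]
        return out.ravel()

    result = lmfit.minimize(residual, params)
    if not result.success:
        raise RuntimeError(f"dose-response fit failed: {result.message}")
    log_ec50 = result.params["log10_ec50"]
    ec50 = 10.0 ** log_ec50.value
    ec50_se = (ec50 * np.log(10) * log_ec50.stderr
               if log_ec50.stderr is not None else np.nan)
    amp = np.array([result.params[f"amp_{s}"].value
                    for s in range(dataset.n_states)])
    base = np.array([result.params[f"base_{s}"].value
                     for s in range(dataset.n_states)])
    identifiable = bool(np.max(np.abs(amp)) > min_amplitude)
    if not identifiable:
        raise RuntimeError("EC50 unidentifiable: all amplitudes are ~0")
    extrapolated = not (pos.min() <= ec50 <= pos.max())
    return DoseResponseFit(ec50=float(ec50), ec50_se=float(ec50_se),
                           hill=float(hill), base=base, amp=amp,
                           identifiable=identifiable,
                           extrapolated=extrapolated,
                           redchi=float(result.redchi),
                           state_labels=dataset.state_labels)
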