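"""Synthetic saturation-binding titrations.

Total signal follows the one-site model with a linear nonspecific term,
multiplied by lognormal noise of a given coefficient of variation (the
noise of bead-proximity counting assays scales with the signal); paired
nonspecific wells carry the linear term only, under the same noise model.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ..binding import SaturationBindingDataset

__all__ = ["simulate_binding", "log_spaced_concentrations"]


def log_spaced_concentrations(lo_nM: float, hi_nM: float,
                              n: int = 12) -> np.ndarray:
    """Logarithmically spaced titration design (nM)."""
    return np.geomspace(lo_nM, hi_nM, n)


def simulate_binding(kd_nM: float, bmax: float, ns_slope: float,
                     concentrations_nM: Sequence[float], cv: float = 0.05,
                     replicates: int = 3, seed: int = 0,
                     construct: str = "", ligand: str = ""
                     ) -> SaturationBindingDataset:
    """Simulate total + paired nonspecific wells; deterministic under seed."""
    if not (kd_nM > 0 and bmax > 0):
        raise ValueError("kd and bmax must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    conc = np.asarray(concentrations_nM, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    if cv > 0:
        sig2 = np.log1p(cv ** 2)
        mu, sigma = -0.5 * sig2, np.sqrt(sig2)   # unit-mean multiplier
    rows = []
    for rep in range(replicates):
        for is_ns in (False, True):
            mean = ns_slope * conc
            if not is_ns:
                mean = mean + bmax * conc / (kd_nM + conc)
            if cv > 0:
                mean = mean * rng.lognormal(mu, sigma, size=conc.size)
            for c, s in zip(conc, mean):
                rows.append((c, s, rep, is_ns))
    df = pd.DataFrame(rows, columns=["concentration_nM", "signal",
                                     "replicate", "nonspecific"])
    return SaturationBindingDataset(data=df, construct=construct,
                                    ligand=ligand)
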