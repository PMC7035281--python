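"""Equilibrium saturation-binding analysis.

One-site specific binding with a linear nonspecific background:

    total(L) = Bmax * L / (Kd + L) + m * L
    nonspecific(L) = m * L

fitted jointly by nonlinear least squares (default), or after pairwise
subtraction of matched nonspecific wells (``subtract_paired=True``, the
classic cold-ligand background subtraction).  Curves are reported both in
signal units and normalized to percent of the fitted Bmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np
import pandas as pd

__all__ = ["SaturationBindingDataset", "BindingFit", "fit_one_site",
           "fold_change"]


@dataclass
class SaturationBindingDataset:
    """Titration rows: (concentration in nM, total signal, replicate index,
    nonspecific flag), with free-form construct/ligand labels."""

    data: pd.DataFrame
    construct: str = ""
    ligand: str = ""

    REQUIRED = ("concentration_nM", "signal", "replicate", "nonspecific")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        if (self.data["concentration_nM"] <= 0).any():
            raise ValueError("concentrations must be positive")
        self.data = self.data.copy()
        self.data["nonspecific"] = self.data["nonspecific"].astype(bool)

    @property
    def specific_rows(self) -> pd.DataFrame:
        return self.data[~self.data["nonspecific"]]

    @property
    def nonspecific_rows(self) -> pd.DataFrame:
        return self.data[self.data["nonspecific"]]

    def n_concentrations(self) -> int:
        return self.specific_rows["concentration_nM"].nunique()


@dataclass
class BindingFit:
    """Fitted one-site parameters with standard errors from the covariance."""

    kd_nM: float
    kd_se: float
    bmax: float
    bmax_se: float
    ns_slope: float
    ns_slope_se: float
    residual_rms: float
    n_points: int
    at_bounds: bool = False
    construct: str = ""

    def __post_init__(self) -> None:
        if not (self.kd_nM > 0 and self.bmax > 0):
            raise ValueError("Kd and Bmax must be positive")
        if min(self.kd_se, self.bmax_se, self.ns_slope_se) < 0:
            raise ValueError("standard errors must be non-negative")

    def specific(self, conc_nM: np.ndarray) -> np.ndarray:
        conc_nM = np.asarray(conc_nM, float)
        return self.bmax * conc_nM / (self.kd_nM + conc_nM)

    def percent_of_max(self, conc_nM: np.ndarray) -> np.ndarray:
        """Specific binding as a percentage of the fitted Bmax."""
        return 100.0 * self.specific(conc_nM) / self.bmax


def _one_site(params: lmfit.Parameters, conc: np.ndarray,
              is_ns: np.ndarray) -> np.ndarray:
    kd = params["kd"].value
    bmax = params["bmax"].value
    m = params["ns_slope"].value
    spec = np.where(is_ns, 0.0, bmax * conc / (kd + conc))
    return spec + m * conc


def fit_one_site(dataset: SaturationBindingDataset,
                 subtract_paired: bool = False,
                 weighting: str = "relative",
                 kd_max_nM: float = 1e7) -> BindingFit:
    """Fit the one-site model to a saturation dataset.

    ``subtract_paired`` averages the nonspecific wells per concentration and
    subtracts them from the matching total wells before fitting the specific
    term alone; the default fits specific + linear nonspecific jointly.

    ``weighting="relative"`` (default) minimizes relative residuals, the
    right objective when measurement noise scales with the signal (as in
    bead-proximity counting); ``"uniform"`` minimizes absolute residuals.
    """
    if weighting not in ("relative", "uniform"):
        raise ValueError("weighting must be 'relative' or 'uniform'")
    if dataset.n_concentrations() < 4:
        raise ValueError("at least 4 distinct concentrations are required")
    df = dataset.data
    if subtract_paired and len(dataset.nonspecific_rows):
        ns_mean = (dataset.nonspecific_rows
                   .groupby("concentration_nM")["signal"].mean())
        spec = dataset.specific_rows.copy()
        spec["signal"] = (spec["signal"].to_numpy()
                          - ns_mean.reindex(spec["concentration_nM"])
                          .fillna(0.0).to_numpy())
        conc = spec["concentration_nM"].to_numpy(float)
        signal = spec["signal"].to_numpy(float)
        is_ns = np.zeros(conc.size, dtype=bool)
        vary_ns = False
    else:
        conc = df["concentration_nM"].to_numpy(float)
        signal = df["signal"].to_numpy(float)
        is_ns = df["nonspecific"].to_numpy(bool)
        vary_ns = bool(is_ns.any())

    params = lmfit.Parameters()
    top = float(np.max(signal))
    params.add("bmax", value=max(top, 1e-12), min=1e-12)
    params.add("kd", value=float(np.median(conc)), min=1e-12, max=kd_max_nM)
    params.add("ns_slope", value=0.0, vary=vary_ns)

    floor = 1e-8 * max(1.0, float(np.abs(signal).max()))

    def residual(p: lmfit.Parameters) -> np.ndarray:
        res = _one_site(p, conc, is_ns) - signal
        if weighting == "relative":
            model = _one_site(p, conc, is_ns)
            res = res / np.maximum(np.abs(model), floor)
        return res

    result = lmfit.minimize(residual, params)
    if not result.success:
        raise RuntimeError(f"one-site fit did not converge: {result.message}")
    kd = result.params["kd"]
    bmax = result.params["bmax"]
    ns = result.params["ns_slope"]
    at_bounds = bool(kd.value >= 0.999 * kd_max_nM or kd.value <= 2e-12)
    return BindingFit(
        kd_nM=float(kd.value), kd_se=float(kd.stderr or 0.0),
        bmax=float(bmax.value), bmax_se=float(bmax.stderr or 0.0),
        ns_slope=float(ns.value), ns_slope_se=float(ns.stderr or 0.0),
        residual_rms=float(np.sqrt(np.mean(result.residual ** 2))),
        n_points=int(conc.size), at_bounds=at_bounds,
        construct=dataset.construct)


def fold_change(fit_a: BindingFit, fit_b: BindingFit) -> tuple[float, float]:
    """Affinity fold-change ``Kd_a / Kd_b`` with first-order propagated SE."""
    if fit_a.at_bounds or fit_b.at_bounds:
        raise ValueError("fold change undefined: a fit hit its Kd bounds")
    ratio = fit_a.kd_nM / fit_b.kd_nM
    rel = np.hypot(fit_a.kd_se / fit_a.kd_nM, fit_b.kd_se / fit_b.kd_nM)
    return float(ratio), float(ratio * rel)
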