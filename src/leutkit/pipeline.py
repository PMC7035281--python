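"""Convenience chains over the analysis stages.

These helpers wire correction -> FRET -> idealization -> kinetics the way
the individual operations are meant to be composed; the CLI and the
example scripts are thin wrappers over them.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .simulate.traces import (GroundTruth, TraceSimConfig, simulate_titration)
from .smfret.correction import (DEFAULT_BLEED_THROUGH, compute_fret,
                                correct_bleed_through)
from .smfret.doseresponse import (DoseResponseDataset, DoseResponseFit,
                                  dose_response_from_titration,
                                  fit_dose_response)
from .smfret.kinetics import OccupancyTable, occupancy
from .smfret.selection import SelectionCriteria, detect_bleach_and_blinks, select_traces
from .smfret.skm import IdealizedPath, StateModel, idealize_batch
from .traces import FluorescenceTrace, FretTrace

__all__ = ["idealize_traces", "titration_occupancies", "titration_ec50_fit"]


def idealize_traces(traces: Sequence[FluorescenceTrace],
                    model: StateModel = StateModel(),
                    bleed_fraction: float = DEFAULT_BLEED_THROUGH,
                    criteria: Optional[SelectionCriteria] = None,
                    detect_photophysics: bool = False
                    ) -> tuple[list[FretTrace], list[IdealizedPath]]:
    """Correct, (optionally) select, and idealize a set of raw traces.

    With ``criteria`` given, the five-criterion filter runs first and only
    accepted traces are idealized.  ``detect_photophysics`` additionally
    derives the dark mask from detected blinks/bleach even when no
    selection is requested (slower; off by default for clean simulations).
    """
    if criteria is not None:
        frets, _ = select_traces(traces, criteria, bleed_fraction)
    else:
        frets = []
        for t in traces:
            corr = (t if t.acceptor_is_corrected
                    else correct_bleed_through(t, bleed_fraction))
            if detect_photophysics:
                rep = detect_bleach_and_blinks(corr)
                frets.append(compute_fret(corr, dark_mask=rep.dark_mask(),
                                          bleach_frame=rep.bleach_frame))
            else:
                frets.append(compute_fret(corr))
    return frets, idealize_batch(frets, model)


def titration_occupancies(titration: dict[float, tuple[list[FluorescenceTrace],
                                                       list[GroundTruth]]],
                          model: StateModel = StateModel(),
                          bleed_fraction: float = DEFAULT_BLEED_THROUGH
                          ) -> dict[float, OccupancyTable]:
    """Ensemble occupancies of the non-dark states per concentration."""
    out = {}
    for c, (traces, _) in titration.items():
        _, paths = idealize_traces(traces, model, bleed_fraction)
        out[c] = occupancy(paths, n_states=model.n_states)
    return out


def titration_ec50_fit(config: TraceSimConfig,
                       concentrations: Sequence[float],
                       model: StateModel = StateModel(),
                       hill: float = 1.0
                       ) -> tuple[DoseResponseFit, DoseResponseDataset]:
    """Simulate a titration and recover its EC50 end to end."""
    titration = simulate_titration(config, concentrations)
    occ = titration_occupancies(titration, model,
                                config.bleed_through_fraction)
    dataset = dose_response_from_titration(occ)
    return fit_dose_response(dataset, hill=hill), dataset
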