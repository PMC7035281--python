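"""Ion coordination shells.

The two sodium sites of the transporter are characterized by the polar
(O/N) atoms within a cutoff of the ion: six coordinating atoms indicate an
octahedral-like shell, five a trigonal-bipyramidal-like one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .frame import MolecularFrame

__all__ = ["CoordinationEntry", "CoordinationReport", "ion_coordination"]

_POLAR_ELEMENTS = ("O", "N")
_COORDINATED_CATEGORIES = ("protein", "substrate", "water")


@dataclass
class CoordinationEntry:
    chain: str
    resid: int
    resname: str
    atom_name: str
    distance: float


@dataclass
class CoordinationReport:
    ion_resid: int
    ion_name: str
    cutoff: float
    entries: list[CoordinationEntry]

    @property
    def count(self) -> int:
        return len(self.entries)

    @property
    def geometry(self) -> str:
        if self.count == 6:
            return "octahedral-like"
        if self.count == 5:
            return "trigonal-bipyramidal-like"
        return "other"


def ion_coordination(frame: MolecularFrame, ion_resid: int,
                     chain: Optional[str] = None,
                     cutoff: float = 3.0) -> CoordinationReport:
    """Polar protein/substrate/water atoms within ``cutoff`` Angstrom of the
    named ion, sorted by distance."""
    im = frame.mask(category="ion", resid=ion_resid, chain=chain)
    idx = np.flatnonzero(im)
    if idx.size == 0:
        raise KeyError(f"no ion with residue number {ion_resid}"
                       f" (chain={chain or '*'})")
    if idx.size > 1:
        raise KeyError(f"ion residue {ion_resid} is ambiguous; select a chain")
    ion_xyz = frame.coords[idx[0]]

    cand = np.isin(frame.category, _COORDINATED_CATEGORIES)
    cand &= np.isin(frame.element, _POLAR_ELEMENTS)
    dist = np.linalg.norm(frame.coords - ion_xyz, axis=1)
    cand &= dist <= cutoff
    order = np.flatnonzero(cand)[np.argsort(dist[cand])]
    entries = [CoordinationEntry(chain=str(frame.chain[k]),
                                 resid=int(frame.resid[k]),
                                 resname=str(frame.resname[k]),
                                 atom_name=str(frame.atom_name[k]),
                                 distance=float(dist[k]))
               for k in order]
    return CoordinationReport(ion_resid=int(ion_resid),
                              ion_name=str(frame.atom_name[idx[0]]),
                              cutoff=float(cutoff), entries=entries)
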