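"""Intracellular-gate collective variables.

The cytoplasmic pathway of the transporter is occluded by two interaction
networks: the R5-D369 salt bridge and the Y268-Q361 hydrogen bond.  Both are
measured as the *minimum* distance over the chemically relevant polar atom
sets, which is robust to side-chain rotamer flips.  The rotamer of Y268
itself is tracked through its chi1 dihedral (N-CA-CB-CG): values near 180
degrees are "out" (gate-open-prone), gauche values are "in".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .frame import MolecularFrame

__all__ = ["GateDefinition", "gate_distances", "dihedral", "chi1",
           "classify_chi1", "substrate_com"]


@dataclass(frozen=True)
class GateDefinition:
    """Atom sets defining the two gate distances and the chi1 residue."""

    salt_bridge_a: tuple[int, tuple[str, ...]] = (5, ("NE", "NH1", "NH2"))
    salt_bridge_b: tuple[int, tuple[str, ...]] = (369, ("OD1", "OD2"))
    hbond_a: tuple[int, tuple[str, ...]] = (268, ("OH",))
    hbond_b: tuple[int, tuple[str, ...]] = (361, ("OE1", "NE2"))
    chi1_residue: int = 268


def _min_pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def gate_distances(frame: MolecularFrame,
                   gates: GateDefinition = GateDefinition(),
                   chain: Optional[str] = None) -> tuple[float, float]:
    """(salt-bridge distance, hydrogen-bond distance) in Angstrom.

    Each is the minimum pairwise Euclidean distance over the configured
    atom sets; a missing named atom raises :class:`MissingAtomError`.
    """
    d1 = _min_pair_distance(
        frame.group_coords(*gates.salt_bridge_a, chain=chain),
        frame.group_coords(*gates.salt_bridge_b, chain=chain))
    d2 = _min_pair_distance(
        frame.group_coords(*gates.hbond_a, chain=chain),
        frame.group_coords(*gates.hbond_b, chain=chain))
    return d1, d2


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points
    using the IUPAC sign convention."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    deg = float(np.degrees(np.arctan2(y, x)))
    if deg <= -180.0:
        deg += 360.0
    return deg


def chi1(frame: MolecularFrame, resid: int,
         chain: Optional[str] = None) -> float:
    """chi1 (N-CA-CB-CG) of a residue in degrees, in (-180, 180].

    Residues lacking a CG (Gly, Ala) raise :class:`MissingAtomError`.
    """
    atoms = [frame.atom(resid, name, chain=chain)
             for name in ("N", "CA", "CB", "CG")]
    return dihedral(*atoms)


def classify_chi1(angle_deg: float, out_threshold: float = 120.0) -> str:
    """"out" rotamer (|chi1| >= threshold, i.e. near anti/180 degrees)
    versus "in" (gauche)."""
    return "out" if abs(angle_deg) >= out_threshold else "in"


def substrate_com(frame: MolecularFrame) -> np.ndarray:
    """Mass-weighted center of the substrate atoms (standard atomic masses;
    hydrogens contribute when present)."""
    m = frame.mask(category="substrate")
    if not m.any():
        raise ValueError("frame contains no substrate atoms")
    sub = frame.subset(m)
    w = sub.masses()
    return (sub.coords * w[:, None]).sum(axis=0) / w.sum()
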