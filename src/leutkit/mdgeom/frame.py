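"""Labeled atomic coordinate frame.

A :class:`MolecularFrame` is a column-oriented table of atoms (chain,
residue number/name, atom name, category, x/y/z in Angstrom) for one
snapshot — a crystal structure or one model of a multi-model trajectory.
Categories (protein / lipid / water / substrate / ion / unknown) drive the
hydration and coordination analyses and are assigned from residue names at
read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["MolecularFrame", "MissingAtomError", "ATOMIC_MASSES",
           "BACKBONE_ATOMS"]

#: Standard atomic masses (u) for the elements that occur in these systems.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "ZN": 65.38, "F": 18.998,
}

#: Peptide backbone atom names (the convention used by the distance criteria).
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_MONATOMIC = {"NA", "CL", "K", "MG", "ZN"}


class MissingAtomError(KeyError):
    """A named reference atom could not be resolved in the frame."""


def guess_element(atom_name: str, category: str = "") -> str:
    name = atom_name.strip().upper()
    if category == "ion" and name in _MONATOMIC:
        return name
    for ch in name:
        if ch.isalpha():
            return ch
    return "C"


@dataclass
class MolecularFrame:
    """One labeled coordinate snapshot (all distances in Angstrom)."""

    chain: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    category: np.ndarray
    coords: np.ndarray
    element: Optional[np.ndarray] = None
    frame_index: int = 0
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype="U4")
        self.resid = np.asarray(self.resid, dtype=int)
        self.resname = np.asarray(self.resname, dtype="U5")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.category = np.asarray(self.category, dtype="U10")
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        for name, arr in (("chain", self.chain), ("resid", self.resid),
                          ("resname", self.resname),
                          ("atom_name", self.atom_name),
                          ("category", self.category)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.element is None:
            self.element = np.array(
                [guess_element(a, c)
                 for a, c in zip(self.atom_name, self.category)], dtype="U2")
        else:
            self.element = np.asarray(self.element, dtype="U2")
        keys = set(zip(self.chain.tolist(), self.resid.tolist(),
                       self.atom_name.tolist()))
        if len(keys) != n:
            raise ValueError("(chain, residue number, atom name) must be unique")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def mask(self, category: Optional[str] = None,
             resid: Optional[int | Sequence[int]] = None,
             atom_names: Optional[Iterable[str]] = None,
             chain: Optional[str] = None) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if category is not None:
            m &= self.category == category
        if resid is not None:
            resids = np.atleast_1d(resid)
            m &= np.isin(self.resid, resids)
        if atom_names is not None:
            m &= np.isin(self.atom_name, list(atom_names))
        if chain is not None:
            m &= self.chain == chain
        return m

    def subset(self, m: np.ndarray) -> "MolecularFrame":
        return MolecularFrame(
            chain=self.chain[m], resid=self.resid[m], resname=self.resname[m],
            atom_name=self.atom_name[m], category=self.category[m],
            coords=self.coords[m], element=self.element[m],
            frame_index=self.frame_index, box=self.box)

    def atom(self, resid: int, atom_name: str,
             chain: Optional[str] = None) -> np.ndarray:
        """Coordinates of a single named atom; raises a named error listing
        chain/residue/atom when absent or ambiguous."""
        m = self.mask(resid=resid, atom_names=[atom_name], chain=chain)
        idx = np.flatnonzero(m)
        where = f"chain={chain or '*'} residue {resid} atom {atom_name}"
        if idx.size == 0:
            raise MissingAtomError(f"no atom matching {where}")
        if idx.size > 1:
            raise MissingAtomError(
                f"{where} is ambiguous ({idx.size} matches); select a chain")
        return self.coords[idx[0]]

    def group_coords(self, resid: int | Sequence[int],
                     atom_names: Iterable[str],
                     chain: Optional[str] = None) -> np.ndarray:
        m = self.mask(resid=resid, atom_names=atom_names, chain=chain)
        if not m.any():
            raise MissingAtomError(
                f"no atoms matching residue(s) {resid} atoms "
                f"{sorted(atom_names)} (chain={chain or '*'})")
        return self.coords[m]

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, 12.011) for e in self.element])

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "MolecularFrame":
        """Apply a rigid (or improper) transform x -> R x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        return replace(self, coords=self.coords @ rotation.T + translation)
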