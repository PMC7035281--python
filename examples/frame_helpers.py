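"""Tiny frame builder shared by the example scripts."""

import numpy as np

from leutkit.mdgeom import MolecularFrame


def make_gate_frame() -> MolecularFrame:
    """A minimal frame holding both gate atom sets and the Y268 chi1 atoms
    in a closed-gate geometry (salt bridge ~4 A, hydrogen bond ~3 A)."""
    atoms = [
        ("A", 5, "ARG", "NE", "protein", (0.0, 0.0, 10.0)),
        ("A", 5, "ARG", "NH1", "protein", (0.0, 0.0, 4.0)),
        ("A", 5, "ARG", "NH2", "protein", (0.0, 3.0, 10.0)),
        ("A", 369, "ASP", "OD1", "protein", (0.0, 0.0, 0.0)),
        ("A", 369, "ASP", "OD2", "protein", (0.0, 8.0, 0.0)),
        ("A", 268, "TYR", "N", "protein", (21.0, 1.0, 0.0)),
        ("A", 268, "TYR", "CA", "protein", (20.0, 0.0, 0.0)),
        ("A", 268, "TYR", "CB", "protein", (20.0, 0.0, 1.5)),
        ("A", 268, "TYR", "CG", "protein", (19.0, -1.0, 1.5)),
        ("A", 268, "TYR", "OH", "protein", (20.0, 0.0, 5.0)),
        ("A", 361, "GLN", "OE1", "protein", (20.0, 3.0, 5.0)),
        ("A", 361, "GLN", "NE2", "protein", (20.0, -5.0, 5.0)),
    ]
    return MolecularFrame(
        chain=np.array([a[0] for a in atoms]),
        resid=np.array([a[1] for a in atoms]),
        resname=np.array([a[2] for a in atoms]),
        atom_name=np.array([a[3] for a in atoms]),
        category=np.array([a[4] for a in atoms]),
        coords=np.array([a[5] for a in atoms], dtype=float))
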