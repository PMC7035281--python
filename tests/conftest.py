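"""Shared fixtures and frame-building helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from leutkit.mdgeom import MolecularFrame
from leutkit.traces import FretTrace


def build_frame(atoms, frame_index: int = 0) -> MolecularFrame:
    """Build a frame from (chain, resid, resname, atom_name, category, xyz)
    tuples."""
    return MolecularFrame(
        chain=np.array([a[0] for a in atoms]),
        resid=np.array([a[1] for a in atoms]),
        resname=np.array([a[2] for a in atoms]),
        atom_name=np.array([a[3] for a in atoms]),
        category=np.array([a[4] for a in atoms]),
        coords=np.array([a[5] for a in atoms], dtype=float),
        frame_index=frame_index)


def fret_from_array(values, frame_period: float = 0.025,
                    molecule_id: str = "0") -> FretTrace:
    values = np.asarray(values, dtype=float)
    return FretTrace(efficiency=values, dark=np.zeros(values.size, bool),
                     frame_period=frame_period, molecule_id=molecule_id)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(12345))
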