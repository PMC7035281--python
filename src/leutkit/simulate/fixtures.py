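"""Synthetic coordinate-frame fixtures for the hydration analysis.

Builds a frame containing the reference atoms the vestibule/channel water
criteria refer to (substrate heavy atoms, the z-bound atoms, the backbone
exclusion residues, the channel residue), single-atom lipids and 3-atom
rigid waters planted so that each water either satisfies every membership
criterion or violates exactly one labeled criterion.  Every water carries a
ground-truth label vector computed by a deliberately simple per-water,
per-criterion evaluation (plain loops over atoms) that is independent of
the vectorized analysis code it is used to test.

The layout places each reference group on its own axis with >= 0.3 A of
slack between every planted water and every threshold it must clear, so
the intended category is guaranteed under the default jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..mdgeom.frame import MolecularFrame
from ..mdgeom.hydration import CRITERION_NAMES, HydrationCriteria

__all__ = ["FrameFixtureConfig", "WaterLabel", "make_frame_fixture",
           "PLANT_CATEGORIES"]

#: Planting categories: all criteria satisfied, or exactly one violated.
PLANT_CATEGORIES = (
    "satisfies_all", "violates_substrate_com", "violates_lipid",
    "violates_z", "violates_L495", "violates_L257", "violates_trio",
    "violates_A198",
)

# nominal centers (Angstrom, before the box shift) and jitter radii of each
# planting zone; chosen so every zone clears every non-target threshold.
_ZONES = {
    "satisfies_all": ((0.0, 0.0, 3.0), 2.0),
    "violates_substrate_com": ((16.2, 0.0, 0.0), 0.15),
    "violates_lipid": ((0.0, -4.0, -5.0), 0.3),
    "violates_z": ((2.0, 0.0, 10.2), 0.25),
    "violates_L495": ((-6.5, 0.0, 0.0), 0.3),
    "violates_L257": ((0.0, -9.0, 0.0), 0.3),
    "violates_trio": ((1.5, 10.5, 0.0), 0.2),
    "violates_A198": ((-5.0, 0.0, 7.5), 0.15),
}

_VIOLATED_CRITERION = {
    "satisfies_all": None,
    "violates_substrate_com": "within_substrate_com",
    "violates_lipid": "lipid_ok",
    "violates_z": "z_in_bounds",
    "violates_L495": "outside_L495",
    "violates_L257": "outside_L257",
    "violates_trio": "outside_V276_L280_L420",
    "violates_A198": "near_A198",
}


@dataclass
class FrameFixtureConfig:
    """Counts of planted waters per category plus lipid/box settings."""

    n_satisfies_all: int = 5
    n_violates_substrate_com: int = 0
    n_violates_lipid: int = 0
    n_violates_z: int = 0
    n_violates_L495: int = 0
    n_violates_L257: int = 0
    n_violates_trio: int = 0
    n_violates_A198: int = 0
    n_random: int = 0
    lipid_atom_count: int = 10
    box: float = 60.0
    seed: int = 0

    def count(self, category: str) -> int:
        return getattr(self, f"n_{category}")

    def __post_init__(self) -> None:
        for cat in PLANT_CATEGORIES:
            if self.count(cat) < 0:
                raise ValueError("planted water counts must be >= 0")
        if self.n_random < 0 or self.lipid_atom_count < 0:
            raise ValueError("counts must be >= 0")
        # the reference assembly spans ~46 A and the widest criterion ball is
        # 2 x 15 A; smaller boxes cannot hold the plantings.
        if self.box < 48.0:
            raise ValueError("box must be at least 48 A to hold the plantings")


@dataclass
class WaterLabel:
    """Ground truth for one planted water."""

    resid: int
    category: str                  # planting category or "random"
    criteria: dict[str, bool]      # pass/fail of every individual criterion
    vestibule: bool
    channel: bool


def _reference_atoms() -> list[tuple[str, int, str, str, str, tuple]]:
    """(chain, resid, resname, atom, category, xyz) of the fixed assembly."""
    atoms: list[tuple[str, int, str, str, str, tuple]] = []
    # substrate: 12 carbons symmetric about the origin -> COM exactly (0,0,0)
    for k in range(6):
        ang = math.pi * k / 3.0
        x, y = 1.4 * math.cos(ang), 1.4 * math.sin(ang)
        atoms.append(("S", 601, "LPH", f"C{k + 1}", "substrate", (x, y, 0.5)))
        atoms.append(("S", 601, "LPH", f"C{k + 7}", "substrate", (x, y, -0.5)))
    # z-slab bounds
    atoms.append(("A", 259, "PHE", "CB", "protein", (0.0, 0.0, -9.0)))
    atoms.append(("A", 13, "GLY", "CA", "protein", (0.0, 0.0, 9.0)))

    def backbone(resid, resname, center):
        cx, cy, cz = center
        # first atom exactly at the nominal center (distance guarantees)
        return [("A", resid, resname, "N", "protein", (cx, cy, cz)),
                ("A", resid, resname, "CA", "protein", (cx + 0.4, cy, cz)),
                ("A", resid, resname, "C", "protein", (cx, cy + 0.4, cz)),
                ("A", resid, resname, "O", "protein", (cx + 0.4, cy + 0.4, cz))]

    atoms += backbone(198, "ALA", (5.0, 0.0, 0.0))     # channel residue
    atoms += backbone(495, "LEU", (-13.0, 0.0, 0.0))
    atoms += backbone(257, "LEU", (0.0, -13.0, 0.0))
    atoms += backbone(276, "VAL", (0.0, 22.0, 0.0))
    atoms += backbone(280, "LEU", (0.0, 22.0, 2.0))
    atoms += backbone(420, "LEU", (0.0, 22.0, -2.0))
    return atoms


def _lipid_atoms(n_extra: int) -> list[tuple]:
    """Anchor lipid (used by the lipid-violation zone) plus a grid of extra
    single-atom lipids kept > 5 A from every planting zone."""
    atoms = [("L", 2000, "LIP", "C1", "lipid", (0.0, -6.0, -7.0))]
    for i in range(n_extra):
        x = -12.0 + 3.0 * (i % 9)
        z = -6.0 + 3.0 * ((i // 9) % 5)
        y = -15.0 - 3.0 * (i // 45)
        atoms.append(("L", 2001 + i, "LIP", "C1", "lipid", (x, y, z)))
    return atoms


def _direct_labels(oxygen: tuple[float, float, float],
                   ref: list[tuple], criteria: HydrationCriteria
                   ) -> dict[str, bool]:
    """Brute-force per-criterion evaluation of one water oxygen, written as
    plain loops (the generator-side oracle)."""
    bb = set(criteria.backbone_atoms)
    sub = [a[5] for a in ref if a[4] == "substrate"]
    lipids = [a[5] for a in ref if a[4] == "lipid"]

    def dist(p, q):
        return math.dist(p, q)

    def min_to_backbone(resids):
        ds = [dist(oxygen, a[5]) for a in ref
              if a[4] == "protein" and a[1] in resids and a[3] in bb]
        return min(ds) if ds else math.inf

    com = tuple(sum(p[k] for p in sub) / len(sub) for k in range(3))
    (r1, a1), (r2, a2) = criteria.z_bound_atoms
    z1 = next(a[5][2] for a in ref if a[1] == r1 and a[3] == a1)
    z2 = next(a[5][2] for a in ref if a[1] == r2 and a[3] == a2)
    lo, hi = min(z1, z2), max(z1, z2)

    out = {
        "within_substrate_com":
            dist(oxygen, com) <= criteria.substrate_com_radius,
        "lipid_ok": all(dist(oxygen, p) > criteria.lipid_exclusion
                        for p in lipids),
        "z_in_bounds": bool(lo <= oxygen[2] <= hi),
        "outside_L495":
            min_to_backbone({criteria.excl_L495_resid})
            > criteria.excl_L495_radius,
        "outside_L257":
            min_to_backbone({criteria.excl_L257_resid})
            > criteria.excl_L257_radius,
        "outside_V276_L280_L420":
            min_to_backbone(set(criteria.excl_trio_resids))
            > criteria.excl_trio_radius,
        "near_A198":
            min_to_backbone({criteria.channel_resid})
            <= criteria.channel_radius,
    }
    return out


def make_frame_fixture(config: FrameFixtureConfig
                       ) -> tuple[MolecularFrame, list[WaterLabel]]:
    """Build a labeled fixture frame.

    Raises if a planted water's ground-truth label vector does not match its
    requested category (geometrically infeasible planting).
    """
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(config.seed)))
    criteria = HydrationCriteria()
    ref = _reference_atoms() + _lipid_atoms(config.lipid_atom_count)

    waters: list[tuple[int, str, tuple[float, float, float]]] = []
    resid = 1000
    for cat in PLANT_CATEGORIES:
        center, jitter = _ZONES[cat]
        for _ in range(config.count(cat)):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = jitter * rng.random() ** (1.0 / 3.0)
            pos = tuple(float(x) for x in np.asarray(center) + r * u)
            waters.append((resid, cat, pos))
            resid += 1
    half = config.box / 2.0
    for _ in range(config.n_random):
        pos = tuple(float(x) for x in rng.uniform(-half + 2.0, half - 2.0, 3))
        waters.append((resid, "random", pos))
        resid += 1

    labels = []
    for rid, cat, pos in waters:
        tab = _direct_labels(pos, ref, criteria)
        vest = all(tab[name] for name in CRITERION_NAMES[:-1])
        labels.append(WaterLabel(resid=rid, category=cat, criteria=tab,
                                 vestibule=vest,
                                 channel=vest and tab["near_A198"]))
        if cat == "satisfies_all" and not (vest and tab["near_A198"]):
            raise ValueError(f"infeasible planting for water {rid} ({cat})")
        if cat != "random" and cat != "satisfies_all":
            target = _VIOLATED_CRITERION[cat]
            ok = all(tab[name] != (name == target) for name in CRITERION_NAMES)
            if not ok:
                raise ValueError(f"infeasible planting for water {rid} ({cat})")

    chains, resids, resnames, names, cats, xyz = [], [], [], [], [], []
    for ch, rid, rn, an, cat, p in ref:
        chains.append(ch)
        resids.append(rid)
        resnames.append(rn)
        names.append(an)
        cats.append(cat)
        xyz.append(p)
    for rid, _, p in waters:
        for an, off in (("O", (0.0, 0.0, 0.0)),
                        ("H1", (0.76, 0.59, 0.0)),
                        ("H2", (-0.76, 0.59, 0.0))):
            chains.append("W")
            resids.append(rid)
            resnames.append("HOH")
            names.append(an)
            cats.append("water")
            xyz.append(tuple(np.asarray(p) + off))

    coords = np.asarray(xyz, dtype=float) + half
    if coords.min() < 0 or coords.max() > config.box:
        raise ValueError("plantings do not fit in the requested box")
    frame = MolecularFrame(chain=np.array(chains), resid=np.array(resids),
                           resname=np.array(resnames),
                           atom_name=np.array(names),
                           category=np.array(cats), coords=coords,
                           box=np.diag([config.box] * 3).astype(float))
    return frame, labels
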