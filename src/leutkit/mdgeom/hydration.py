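"""Water counting in the intracellular vestibule and release channel.

A water molecule (tested through its oxygen atom only) belongs to the
intracellular vestibule when it simultaneously satisfies a chain of
distance criteria relative to the bound substrate, the lipids and a set of
reference residues; the release *channel* toward the second sodium site is
the part of the vestibule near the A198 backbone.  All thresholds live in
:class:`HydrationCriteria` and every one can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .frame import BACKBONE_ATOMS, MissingAtomError, MolecularFrame
from .gates import substrate_com

__all__ = ["HydrationCriteria", "WaterCounts", "evaluate_criteria",
           "count_waters", "hydration_histogram", "CRITERION_NAMES"]

#: Names of the individual membership criteria, in evaluation order.  All but
#: ``near_A198`` must pass for vestibule membership; ``near_A198`` restricts
#: the vestibule to the channel.
CRITERION_NAMES = ("within_substrate_com", "lipid_ok", "z_in_bounds",
                   "outside_L495", "outside_L257", "outside_V276_L280_L420",
                   "near_A198")


@dataclass(frozen=True)
class HydrationCriteria:
    """Distance thresholds (Angstrom) and reference residues of the
    vestibule/channel membership test."""

    substrate_com_radius: float = 15.0
    lipid_exclusion: float = 5.0
    #: (residue, atom) pair whose z coordinates bound the vestibule slab,
    #: ordered per frame.
    z_bound_atoms: tuple[tuple[int, str], tuple[int, str]] = (
        (259, "CB"), (13, "CA"))
    excl_L495_radius: float = 8.0
    excl_L495_resid: int = 495
    excl_L257_radius: float = 5.0
    excl_L257_resid: int = 257
    excl_trio_radius: float = 13.0
    excl_trio_resids: tuple[int, ...] = (276, 280, 420)
    channel_radius: float = 12.0
    channel_resid: int = 198
    backbone_atoms: tuple[str, ...] = BACKBONE_ATOMS

    def __post_init__(self) -> None:
        for r in (self.substrate_com_radius, self.lipid_exclusion,
                  self.excl_L495_radius, self.excl_L257_radius,
                  self.excl_trio_radius, self.channel_radius):
            if not r > 0:
                raise ValueError("all hydration radii must be positive")


@dataclass
class WaterCounts:
    """Per-frame vestibule/channel water counts and member identities."""

    frame_index: int
    vestibule: int
    channel: int
    vestibule_resids: np.ndarray
    channel_resids: np.ndarray

    def __post_init__(self) -> None:
        if self.channel > self.vestibule:
            raise ValueError("channel waters are a subset of the vestibule")
        if min(self.vestibule, self.channel) < 0:
            raise ValueError("counts must be non-negative")


def _min_dist_to(points: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-point minimum distance to a target atom set."""
    if targets.size == 0:
        return np.full(points.shape[0], np.inf)
    d = np.linalg.norm(points[:, None, :] - targets[None, :, :], axis=-1)
    return d.min(axis=1)


def evaluate_criteria(frame: MolecularFrame,
                      criteria: HydrationCriteria = HydrationCriteria(),
                      chain: Optional[str] = None
                      ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Evaluate every membership criterion for every water oxygen.

    Returns ``(water_resids, table)`` where ``table[name]`` is the boolean
    pass/fail vector of one criterion (see :data:`CRITERION_NAMES`).
    "within r" means distance <= r throughout.
    """
    wmask = frame.mask(category="water", atom_names=["O", "OH2", "OW"])
    if not wmask.any():
        # frames may legitimately contain no waters
        empty = np.zeros(0, dtype=bool)
        return np.zeros(0, dtype=int), {k: empty for k in CRITERION_NAMES}
    ox = frame.coords[wmask]
    resids = frame.resid[wmask]

    com = substrate_com(frame)
    table: dict[str, np.ndarray] = {}
    table["within_substrate_com"] = (
        np.linalg.norm(ox - com, axis=1) <= criteria.substrate_com_radius)

    lipid_xyz = frame.coords[frame.mask(category="lipid")]
    table["lipid_ok"] = _min_dist_to(ox, lipid_xyz) > criteria.lipid_exclusion

    # membrane-normal slab: the water must project between the two bound
    # atoms along the axis through them.  In membrane-aligned frames where
    # the bound atoms are separated purely along z this is exactly the
    # z-coordinate window; the projection form keeps the criterion
    # invariant under rigid motions of the frame.
    (r1, a1), (r2, a2) = criteria.z_bound_atoms
    p1 = frame.atom(r1, a1, chain=chain)
    p2 = frame.atom(r2, a2, chain=chain)
    axis = p2 - p1
    length = np.linalg.norm(axis)
    if length == 0:
        raise ValueError("slab bound atoms coincide")
    t = (ox - p1) @ (axis / length)
    table["z_in_bounds"] = (t >= 0.0) & (t <= length)

    bb = criteria.backbone_atoms
    l495 = frame.group_coords(criteria.excl_L495_resid, bb, chain=chain)
    table["outside_L495"] = _min_dist_to(ox, l495) > criteria.excl_L495_radius
    l257 = frame.group_coords(criteria.excl_L257_resid, bb, chain=chain)
    table["outside_L257"] = _min_dist_to(ox, l257) > criteria.excl_L257_radius
    trio = frame.group_coords(list(criteria.excl_trio_resids), bb, chain=chain)
    table["outside_V276_L280_L420"] = (
        _min_dist_to(ox, trio) > criteria.excl_trio_radius)

    a198 = frame.group_coords(criteria.channel_resid, bb, chain=chain)
    table["near_A198"] = _min_dist_to(ox, a198) <= criteria.channel_radius
    return resids, table


def count_waters(frame: MolecularFrame,
                 criteria: HydrationCriteria = HydrationCriteria(),
                 chain: Optional[str] = None) -> WaterCounts:
    """Vestibule and channel water counts of one frame.

    Vestibule membership requires every criterion except the A198 proximity;
    channel membership additionally requires it.
    """
    resids, table = evaluate_criteria(frame, criteria, chain=chain)
    vestibule = np.ones(resids.size, dtype=bool)
    for name in CRITERION_NAMES[:-1]:
        vestibule &= table[name]
    channel = vestibule & table["near_A198"]
    return WaterCounts(frame_index=frame.frame_index,
                       vestibule=int(vestibule.sum()),
                       channel=int(channel.sum()),
                       vestibule_resids=resids[vestibule],
                       channel_resids=resids[channel])


@dataclass
class HydrationHistogram:
    """Pooled distribution of per-frame water counts."""

    bin_values: np.ndarray       # integer count values
    frequencies: np.ndarray      # pooled frame counts per value
    modes: np.ndarray            # local maxima of the pooled histogram
    pooled_mean: float
    replica_means: np.ndarray


def hydration_histogram(counts: Sequence[Sequence[int]]) -> HydrationHistogram:
    """Pooled histogram, per-replica means and peak locations of per-frame
    water counts; ``counts`` is one integer sequence per replica."""
    replicas = [np.asarray(c, dtype=int) for c in counts if len(c) > 0]
    if not replicas:
        raise ValueError("at least one non-empty replica is required")
    pooled = np.concatenate(replicas)
    values = np.arange(pooled.min(), pooled.max() + 1)
    freqs = np.array([(pooled == v).sum() for v in values])
    padded = np.concatenate([[-1], freqs, [-1]])
    is_peak = (padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:])
    return HydrationHistogram(
        bin_values=values, frequencies=freqs, modes=values[is_peak],
        pooled_mean=float(pooled.mean()),
        replica_means=np.array([r.mean() for r in replicas]))
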