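"""Readers, writers and run configuration.

Trace tables are plain CSV/TSV (dialect autodetected) with one row per
(molecule, frame): columns ``molecule_id, frame_index, donor, acceptor_raw,
condition[, concentration_molar]``.  Coordinate frames are PDB v3.3 files;
MODEL/ENDMDL records delimit the frames of a multi-model file.  Atom
categories (protein/lipid/water/substrate/ion) are assigned from residue
names through a configurable map.

Every numeric default of the package lives in :class:`PipelineConfig`;
unknown keys are rejected and the config travels with every CLI output as
a provenance block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

from .mdgeom.frame import MolecularFrame, guess_element
from .traces import FluorescenceTrace

__all__ = [
    "TraceTableError", "MissingColumnError", "NonContiguousFramesError",
    "DuplicateRowError", "TraceParseError", "read_traces", "write_traces",
    "read_frames", "write_frames", "DEFAULT_CATEGORY_MAP", "PipelineConfig",
    "write_run_manifest",
]


class TraceTableError(ValueError):
    """Malformed trace table."""


class MissingColumnError(TraceTableError):
    pass


class NonContiguousFramesError(TraceTableError):
    pass


class DuplicateRowError(TraceTableError):
    pass


class TraceParseError(TraceTableError):
    pass


_REQUIRED = ("molecule_id", "frame_index", "donor", "acceptor_raw",
             "condition")


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    """Read a trace table (comma or tab separated, autodetected).

    Frames must be contiguous from 0 within each molecule and unique;
    violations raise named errors.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise MissingColumnError(f"trace table is missing columns {missing}")
    for col in ("frame_index", "donor", "acceptor_raw"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2   # 1-based + header line
            raise TraceParseError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at line {row}")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0]) + 2
            raise TraceParseError(f"missing value in column {col!r} "
                                  f"at line {row}")
        df[col] = vals
    traces = []
    for mol, g in df.groupby("molecule_id", sort=False):
        g = g.sort_values("frame_index")
        idx = g["frame_index"].to_numpy(int)
        if np.unique(idx).size != idx.size:
            raise DuplicateRowError(
                f"molecule {mol!r} has duplicate frame indices")
        if idx[0] != 0 or np.any(np.diff(idx) != 1):
            raise NonContiguousFramesError(
                f"molecule {mol!r}: frame_index must run 0..n-1 contiguously")
        conc = None
        if "concentration_molar" in g.columns:
            c = g["concentration_molar"].iloc[0]
            conc = None if pd.isna(c) else float(c)
        period = (float(g["frame_period"].iloc[0])
                  if "frame_period" in g.columns else 0.025)
        traces.append(FluorescenceTrace(
            donor=g["donor"].to_numpy(float),
            acceptor=g["acceptor_raw"].to_numpy(float),
            frame_period=period, molecule_id=str(mol),
            condition=str(g["condition"].iloc[0]), concentration=conc))
    return traces


def write_traces(traces: Iterable[FluorescenceTrace], path: str | Path,
                 sep: str = ",") -> None:
    frames = []
    for t in traces:
        frames.append(pd.DataFrame({
            "molecule_id": t.molecule_id,
            "frame_index": np.arange(t.n_frames),
            "donor": t.donor, "acceptor_raw": t.acceptor,
            "condition": t.condition,
            "concentration_molar": (np.nan if t.concentration is None
                                    else t.concentration),
            "frame_period": t.frame_period,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, sep=sep)


#: Residue-name -> category map used when reading coordinate files.
DEFAULT_CATEGORY_MAP = {
    "HOH": "water", "TIP3": "water", "TIP": "water", "SOL": "water",
    "WAT": "water",
    "POPE": "lipid", "POPG": "lipid", "POPC": "lipid", "LIP": "lipid",
    "NA": "ion", "CL": "ion", "SOD": "ion", "CLA": "ion", "K": "ion",
    "LPH": "substrate",
}

_AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP",
}


def _categorize(res_name: str, hetero: bool,
                category_map: dict[str, str]) -> str:
    name = res_name.strip().upper()
    if name in category_map:
        return category_map[name]
    if name in _AMINO3:
        # amino-acid HETATM records are bound substrate molecules
        return "substrate" if hetero else "protein"
    return "unknown"


def read_frames(path: str | Path,
                category_map: Optional[dict[str, str]] = None
                ) -> Iterator[MolecularFrame]:
    """Yield one :class:`MolecularFrame` per model of a PDB file."""
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()          # AtomArrayStack, (models, atoms, 3)
    coords = stack.coord
    arr = stack[0]
    categories = np.array([_categorize(rn, bool(h), cmap)
                           for rn, h in zip(arr.res_name, arr.hetero)])
    for k in range(coords.shape[0]):
        yield MolecularFrame(
            chain=arr.chain_id.copy(), resid=arr.res_id.copy(),
            resname=arr.res_name.copy(), atom_name=arr.atom_name.copy(),
            category=categories.copy(), coords=np.asarray(coords[k], float),
            element=arr.element.copy(), frame_index=k)


def write_frames(frames: Iterable[MolecularFrame], path: str | Path) -> None:
    """Write frames as a (multi-)model PDB with occupancy 1.00, B 0.00."""
    frames = list(frames)
    pdb = PDBFile()
    arrays = []
    for frame in frames:
        n = frame.n_atoms
        arr = AtomArray(n)
        arr.chain_id = frame.chain
        arr.res_id = frame.resid
        arr.res_name = frame.resname
        arr.atom_name = frame.atom_name
        arr.element = frame.element
        arr.hetero = ~np.isin(frame.category, ["protein"])
        arr.coord = frame.coords
        arr.set_annotation("occupancy", np.ones(n))
        arr.set_annotation("b_factor", np.zeros(n))
        arrays.append(arr)
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        from biotite.structure import stack as biotite_stack
        pdb.set_structure(biotite_stack(arrays))
    pdb.write(str(path))


@dataclass
class PipelineConfig:
    """Every numeric default of the pipeline, in one versioned document."""

    version: int = 1
    bleed_through_fraction: float = 0.165
    state_means: tuple[float, ...] = (0.0, 0.47, 0.63, 0.79)
    frame_period: float = 0.025
    snr_background_min: float = 8.0
    snr_signal_min: float = 5.0
    max_blink_events: int = 3
    min_frames: int = 300
    fret_floor: float = 0.15
    tdp_bin_width: float = 0.05
    hill: float = 1.0
    substrate_com_radius: float = 15.0
    lipid_exclusion: float = 5.0
    excl_L495_radius: float = 8.0
    excl_L257_radius: float = 5.0
    excl_trio_radius: float = 13.0
    channel_radius: float = 12.0
    cv_bin_width: float = 0.25
    coordination_cutoff: float = 3.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.state_means, list):
            cfg.state_means = tuple(cfg.state_means)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["state_means"] = list(d["state_means"])
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def write_run_manifest(out_path: str | Path, config: PipelineConfig,
                       extra: Optional[dict] = None) -> Path:
    """Write the provenance sidecar (<out>.run.json) of a CLI output."""
    import leutkit

    manifest = {"config": config.to_dict(), "config_digest": config.digest(),
                "seed": config.seed, "leutkit_version": leutkit.__version__,
                "numpy_version": np.__version__}
    if extra:
        manifest.update(extra)
    side = Path(str(out_path) + ".run.json")
    side.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return side
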