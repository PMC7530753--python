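"""Checkpoints and trajectory files.

Model and agent checkpoints are containers of named numeric arrays
(numpy ``.npz``) with the geometry/config serialised as JSON strings
alongside.  Trajectories are extended-XYZ text blocks with the column
order ``id type slice x y z`` (type 0 = fluid, 1 = solid) and a comment
line carrying the simulated time, step index, seed and config hash —
readable by common particle-visualisation tools and by the bundled
reader.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .builder import (TubeGeometry, TubeModel, geometry_from_dict,
                      geometry_to_dict)
from .core import BoxGeometry, ParticleSystem, SimulationConfig
from .membrane import BondTable, TetherSet

__all__ = [
    "config_hash",
    "save_model",
    "load_model",
    "Frame",
    "write_trajectory",
    "read_trajectory",
]

CHECKPOINT_VERSION = 1


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _system_arrays(system: ParticleSystem, prefix: str) -> dict:
    return {
        f"{prefix}positions": system.positions,
        f"{prefix}velocities": system.velocities,
        f"{prefix}forces": system.forces,
        f"{prefix}masses": system.masses,
        f"{prefix}densities": system.densities,
        f"{prefix}phase": system.phase,
        f"{prefix}slice_index": system.slice_index,
        f"{prefix}winding": system.winding,
    }


def _system_from(arrays, prefix: str) -> ParticleSystem:
    return ParticleSystem(
        positions=arrays[f"{prefix}positions"],
        velocities=arrays[f"{prefix}velocities"],
        forces=arrays[f"{prefix}forces"],
        masses=arrays[f"{prefix}masses"],
        densities=arrays[f"{prefix}densities"],
        phase=arrays[f"{prefix}phase"],
        slice_index=arrays[f"{prefix}slice_index"],
        winding=arrays[f"{prefix}winding"],
    )


def save_model(model: TubeModel, path) -> None:
    """Write a tube model checkpoint (named-array container)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "geometry": geometry_to_dict(model.geometry),
        "config": model.config.__dict__,
        "axial_length": model.box.axial_length,
        "transverse_extent": model.box.transverse_extent,
    }
    arrays = _system_arrays(model.system, "sys_")
    arrays.update(_system_arrays(model.initial, "init_"))
    arrays.update({
        "bond_i": model.bonds.i,
        "bond_j": model.bonds.j,
        "bond_rest": model.bonds.rest_length,
        "tether_anchors": model.tethers.anchors,
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    })
    np.savez(path, **arrays)


def load_model(path) -> TubeModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"incompatible model checkpoint version {meta.get('version')}")
        geometry = geometry_from_dict(meta["geometry"])
        config = SimulationConfig(**meta["config"])
        box = BoxGeometry(axial_length=meta["axial_length"],
                          transverse_extent=meta["transverse_extent"])
        system = _system_from(data, "sys_")
        initial = _system_from(data, "init_")
        bonds = BondTable(i=data["bond_i"], j=data["bond_j"],
                          rest_length=data["bond_rest"], k=config.k)
        tethers = TetherSet(anchors=data["tether_anchors"],
                            k_tether=config.k_tether)
    return TubeModel(system=system, bonds=bonds, tethers=tethers,
                     geometry=geometry, box=box, config=config,
                     initial=initial)


@dataclass
class Frame:
    step: int
    time: float
    positions: np.ndarray
    phase: np.ndarray
    slice_index: np.ndarray


def write_trajectory(frames: Sequence[Frame], path, seed: int | None = None,
                     cfg_hash: str | None = None) -> None:
    """Extended-XYZ-style dump: one block per frame, columns
    ``id type slice x y z``."""
    if not frames:
        raise ValueError("no frames to write")
    path = Path(path)
    with path.open("w") as fh:
        for fr in frames:
            n = len(fr.positions)
            fh.write(f"{n}\n")
            header = (f'time={fr.time:.9g} step={fr.step} '
                      f'Properties=id:I:1:type:I:1:slice:I:1:pos:R:3')
            if seed is not None:
                header += f" seed={seed}"
            if cfg_hash is not None:
                header += f" config_hash={cfg_hash}"
            fh.write(header + "\n")
            for pid in range(n):
                x, y, z = fr.positions[pid]
                fh.write(f"{pid} {int(fr.phase[pid])} {int(fr.slice_index[pid])} "
                         f"{x:.10e} {y:.10e} {z:.10e}\n")


def read_trajectory(path) -> list:
    """Parse a trajectory written by :func:`write_trajectory`."""
    frames = []
    lines = Path(path).read_text().splitlines()
    pos = 0
    while pos < len(lines):
        n = int(lines[pos])
        header = lines[pos + 1]
        fields = dict(tok.split("=", 1) for tok in header.split()
                      if "=" in tok)
        rows = [lines[pos + 2 + k].split() for k in range(n)]
        positions = np.array([[float(r[3]), float(r[4]), float(r[5])]
                              for r in rows])
        phase = np.array([int(r[1]) for r in rows], dtype=np.int8)
        slice_index = np.array([int(r[2]) for r in rows], dtype=np.int32)
        frames.append(Frame(step=int(fields["step"]),
                            time=float(fields["time"]),
                            positions=positions, phase=phase,
                            slice_index=slice_index))
        pos += 2 + n
    return frames
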