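"""Lattice-spring membrane: Hookean bonds, tether springs and the
axisymmetric contraction actuation.

The tube wall is a lattice of point masses connected by Hookean springs
(stiffness k, rest length close to the nominal spacing r0).  Each wall
particle is additionally tethered to its build position by a weak spring
(stiffness k') that restores the membrane shape after a contraction.
Contractions apply a constant radial force f0 toward the tube axis to all
particles of the chosen section(s); the actuation has no axial component,
so any propulsion of the fluid must emerge from coordination, not from a
direct axial push.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from numba import njit

from .core import BoxGeometry, ParticleSystem, Phase

__all__ = [
    "BondTable",
    "TetherSet",
    "hooke_pair_force",
    "bond_forces",
    "tether_forces",
    "contraction_forces",
    "tether_potential_energy",
]


@dataclass
class BondTable:
    """Spring bonds between solid particles.

    ``rest_length`` is per bond (the as-built pair distance); ``k`` is a
    single stiffness shared by all bonds.
    """

    i: np.ndarray
    j: np.ndarray
    rest_length: np.ndarray
    k: float

    def __post_init__(self) -> None:
        self.i = np.ascontiguousarray(self.i, dtype=np.int64)
        self.j = np.ascontiguousarray(self.j, dtype=np.int64)
        self.rest_length = np.ascontiguousarray(self.rest_length, dtype=np.float64)
        if np.any(self.i == self.j):
            raise ValueError("self-bonds are not allowed")
        key = np.stack((np.minimum(self.i, self.j), np.maximum(self.i, self.j)))
        if len(np.unique(key, axis=1)[0]) != len(self.i):
            raise ValueError("duplicate bonds")

    @property
    def n(self) -> int:
        return len(self.i)


@dataclass
class TetherSet:
    """Anchor positions (one per particle; NaN rows for fluid) and k'."""

    anchors: np.ndarray   # (N, 3), NaN for non-tethered (fluid) particles
    k_tether: float

    def __post_init__(self) -> None:
        self.anchors = np.ascontiguousarray(self.anchors, dtype=np.float64)


def hooke_pair_force(r_ij: float, e_ij: np.ndarray, k: float,
                     r0_bond: float) -> np.ndarray:
    """Force on particle i from a Hookean bond, F = -k (r_ij - r0) e_ij.

    ``e_ij`` points from j to i; a stretched bond (r_ij > r0) therefore
    pulls i toward j.  Antisymmetric under exchange.
    """
    if not r_ij > 0:
        raise ValueError("pair distance must be positive")
    return -k * (r_ij - r0_bond) * np.asarray(e_ij, dtype=np.float64)


@njit(cache=True)
def _bond_forces_kernel(n, bi, bj, rest, k, pos, L):
    forces = np.zeros((n, 3))
    for m in range(len(bi)):
        i = bi[m]
        j = bj[m]
        dx = pos[i, 0] - pos[j, 0]
        if dx > 0.5 * L:
            dx -= L
        elif dx < -0.5 * L:
            dx += L
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r <= 0.0:
            continue
        coef = -k * (r - rest[m]) / r
        forces[i, 0] += coef * dx
        forces[i, 1] += coef * dy
        forces[i, 2] += coef * dz
        forces[j, 0] -= coef * dx
        forces[j, 1] -= coef * dy
        forces[j, 2] -= coef * dz
    return forces


def bond_forces(system: ParticleSystem, box: BoxGeometry,
                bonds: BondTable) -> np.ndarray:
    """Hookean forces over the bond table (minimum image along the axis)."""
    return _bond_forces_kernel(system.n, bonds.i, bonds.j, bonds.rest_length,
                               bonds.k, system.positions, box.axial_length)


def tether_forces(system: ParticleSystem, tethers: TetherSet) -> np.ndarray:
    """F = -k' (x - anchor) on tethered (solid) particles, zero elsewhere."""
    forces = np.zeros((system.n, 3))
    tethered = ~np.isnan(tethers.anchors[:, 0])
    disp = system.positions[tethered] - tethers.anchors[tethered]
    forces[tethered] = -tethers.k_tether * disp
    return forces


def tether_potential_energy(system: ParticleSystem, tethers: TetherSet) -> float:
    tethered = ~np.isnan(tethers.anchors[:, 0])
    disp = system.positions[tethered] - tethers.anchors[tethered]
    return 0.5 * tethers.k_tether * float(np.sum(disp * disp))


def contraction_forces(system: ParticleSystem, active_slices: Iterable[int],
                       f0: float) -> np.ndarray:
    """Radial force of magnitude f0 toward the tube axis (y = z = 0) on
    every solid particle of the active sections.

    The force is purely transverse, so the summed axial component is zero
    for any activation pattern.  A particle exactly on the axis has no
    defined radial direction and receives no force.
    """
    forces = np.zeros((system.n, 3))
    active = set(int(s) for s in active_slices)
    if not active:
        return forces
    mask = (system.phase == Phase.SOLID) & np.isin(
        system.slice_index, np.fromiter(active, dtype=np.int32))
    yz = system.positions[mask, 1:3]
    radius = np.sqrt(np.sum(yz * yz, axis=1))
    ok = radius > 0
    scale = np.zeros_like(radius)
    scale[ok] = -f0 / radius[ok]
    out = np.zeros((mask.sum(), 3))
    out[:, 1:3] = yz * scale[:, None]
    forces[mask] = out
    return forces
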