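"""Fluid-membrane interface forces.

Compenetration of the two phases is prevented by a short-range repulsive
potential acting on fluid-solid pairs,

    U(r) = A [1 + cos(pi r / r0)],   r < r0,   else 0,

which decays smoothly to zero (value and force) at r = r0.  No-slip at
the wall is approximated by letting fluid and solid particles exchange
the same Monaghan-type pair-viscosity force used inside the fluid; solid
particles enter that expression with the constant reference density rho0
(they carry no SPH density of their own).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import BoxGeometry, PairList, ParticleSystem, Phase, SimulationConfig, build_neighbor_list
from .sph import SUPPORT_FACTOR, _dwdr_cubic

__all__ = [
    "repulsive_potential",
    "repulsive_force",
    "interface_forces",
]


def repulsive_potential(r_ij, A: float, r0: float):
    """Interface repulsion energy U(r); 2A at contact, 0 at and beyond r0."""
    r = np.asarray(r_ij, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    out = np.where(r < r0, A * (1.0 + np.cos(np.pi * r / r0)), 0.0)
    return float(out) if out.ndim == 0 else out


def repulsive_force(r_ij: float, e_ij: np.ndarray, A: float,
                    r0: float) -> np.ndarray:
    """Force on i, -dU/dr e_ij = (A pi / r0) sin(pi r / r0) e_ij for r < r0.

    ``e_ij`` points from j to i, so the force pushes the pair apart for
    all 0 < r < r0 and vanishes continuously at r0.
    """
    if not r_ij > 0:
        raise ValueError("pair distance must be positive")
    if r_ij >= r0:
        return np.zeros(3)
    mag = (A * np.pi / r0) * np.sin(np.pi * r_ij / r0)
    return mag * np.asarray(e_ij, dtype=np.float64)


@njit(cache=True)
def _interface_kernel(n, pair_i, pair_j, pair_r, disp, vel, masses, rho,
                      is_fluid, a, b, h, c0, rho0, A, r0_rep):
    forces = np.zeros((n, 3))
    bh2 = b * h * h
    pref_rep = A * np.pi / r0_rep
    for m in range(len(pair_i)):
        i = pair_i[m]
        j = pair_j[m]
        fi = is_fluid[i]
        fj = is_fluid[j]
        if fi == fj:
            continue  # fluid-solid pairs only
        r = pair_r[m]
        if r <= 0.0:
            continue
        dx = disp[m, 0]
        dy = disp[m, 1]
        dz = disp[m, 2]
        fx = 0.0
        fy = 0.0
        fz = 0.0
        # repulsion, smooth cutoff at r0_rep
        if r < r0_rep:
            mag = pref_rep * np.sin(np.pi * r / r0_rep) / r
            fx += mag * dx
            fy += mag * dy
            fz += mag * dz
        # cross-phase viscosity, kernel support cutoff
        dwdr = _dwdr_cubic(r, h)
        if dwdr != 0.0:
            vx = vel[i, 0] - vel[j, 0]
            vy = vel[i, 1] - vel[j, 1]
            vz = vel[i, 2] - vel[j, 2]
            vdotr = vx * dx + vy * dy + vz * dz
            rho_i = rho[i] if fi else rho0
            rho_j = rho[j] if fj else rho0
            pi_ij = -a * h * (c0 / (rho_i + rho_j)) * vdotr / (r * r + bh2)
            coef = -masses[i] * masses[j] * pi_ij * dwdr / r
            fx += coef * dx
            fy += coef * dy
            fz += coef * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return forces


def interface_forces(system: ParticleSystem, box: BoxGeometry,
                     config: SimulationConfig,
                     pairs: PairList | None = None,
                     include_repulsion: bool = True,
                     include_viscous: bool = True) -> np.ndarray:
    """Repulsion plus cross-phase viscous forces on fluid-solid pairs.

    Pairwise antisymmetric, hence momentum conserving.  The two pieces
    can be toggled independently for diagnostics.
    """
    cutoff = max(SUPPORT_FACTOR * config.h, config.r0_repulsive)
    if pairs is None:
        pairs = build_neighbor_list(system, box, cutoff)
    is_fluid = system.phase == Phase.FLUID
    A = config.A_repulsive if include_repulsion else 0.0
    a = config.a if include_viscous else 0.0
    return _interface_kernel(system.n, pairs.i, pairs.j, pairs.dist, pairs.disp,
                             system.velocities, system.masses, system.densities,
                             is_fluid, a, config.b, config.h, config.c0,
                             config.rho0, A, config.r0_repulsive)
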