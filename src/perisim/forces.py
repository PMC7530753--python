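"""Assembly of all force contributions and the physics rollout driver.

One step of the coupled model: wrap positions, rebuild the neighbour
list, refresh summation densities, then sum fluid pressure/viscous
forces, membrane bond and tether forces, interface repulsion and
cross-phase viscosity, the contraction actuation on the active sections,
and any external body acceleration.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .core import (BoxGeometry, ParticleSystem, SimulationConfig,
                   build_neighbor_list, integrate_step, wrap_positions)
from .coupling import interface_forces
from .membrane import BondTable, TetherSet, bond_forces, contraction_forces, tether_forces
from .sph import SUPPORT_FACTOR, compute_density, fluid_pair_forces

__all__ = ["compute_total_forces", "run_steps"]


def compute_total_forces(system: ParticleSystem, box: BoxGeometry,
                         config: SimulationConfig, bonds: BondTable,
                         tethers: TetherSet,
                         active_slices: Iterable[int] = (),
                         body_accel: Sequence[float] | None = None,
                         refresh_density: bool = True) -> np.ndarray:
    """Total force on every particle for the current configuration."""
    cutoff = max(SUPPORT_FACTOR * config.h, config.r0_repulsive)
    pairs = build_neighbor_list(system, box, cutoff)
    if refresh_density:
        compute_density(system, box, config.h, pairs=pairs,
                        rho_solid=config.rho0)
    f = fluid_pair_forces(system, box, config, pairs=pairs)
    f += interface_forces(system, box, config, pairs=pairs)
    f += bond_forces(system, box, bonds)
    f += tether_forces(system, tethers)
    f += contraction_forces(system, active_slices, config.f0)
    if body_accel is not None:
        f += system.masses[:, None] * np.asarray(body_accel, dtype=np.float64)
    return f


def run_steps(system: ParticleSystem, box: BoxGeometry,
              config: SimulationConfig, bonds: BondTable, tethers: TetherSet,
              n_steps: int, active_slices: Iterable[int] = (),
              body_accel: Sequence[float] | None = None,
              velocity_damping: float = 0.0,
              refresh_density: bool = True,
              observer=None) -> ParticleSystem:
    """Advance ``n_steps`` velocity-Verlet steps with a fixed activation.

    ``velocity_damping`` rescales velocities by (1 - damping) after each
    step; used only for build-time settling, never during episodes.
    ``refresh_density=False`` pins the stored densities (hence pressures)
    — a diagnostic mode for incompressible shear problems.
    ``observer(step, system)`` is called after every completed step.
    """
    active = tuple(int(s) for s in active_slices)

    def _cb(sys_: ParticleSystem) -> np.ndarray:
        return compute_total_forces(sys_, box, config, bonds, tethers,
                                    active, body_accel,
                                    refresh_density=refresh_density)

    wrap_positions(system, box)
    system.forces = _cb(system)
    for step in range(n_steps):
        try:
            integrate_step(system, box, _cb, config.dt)
        except FloatingPointError as err:
            raise FloatingPointError(f"{err} at step {step}") from err
        if velocity_damping:
            system.velocities *= (1.0 - velocity_damping)
        if observer is not None:
            observer(step, system)
    return system
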