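"""Particle containers, periodic box, neighbour search and time integration.

The simulation tracks two phases of particles in one flat set of arrays:
SPH fluid particles and lattice-spring membrane (solid) particles.  The
tube axis is the x direction; the box is periodic along x on ``[0, L)``
and unbounded transversally (the membrane confines the fluid).  Winding
counts record periodic crossings so that unwrapped axial coordinates —
and therefore the fluid centre-of-mass displacement used as the learning
reward — are continuous in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Callable

import numpy as np
from numba import njit

__all__ = [
    "Phase",
    "ParticleSystem",
    "BoxGeometry",
    "SimulationConfig",
    "build_neighbor_list",
    "wrap_positions",
    "unwrapped_axial",
    "integrate_step",
]


class Phase(IntEnum):
    FLUID = 0
    SOLID = 1


@dataclass
class ParticleSystem:
    """Per-particle state arrays (SI units).

    ``slice_index`` is the membrane section a solid particle belongs to
    (0..n_slices-1) and -1 for fluid particles.  ``winding`` counts signed
    crossings of the periodic axial boundary.
    """

    positions: np.ndarray       # (N, 3) m
    velocities: np.ndarray      # (N, 3) m s^-1
    forces: np.ndarray          # (N, 3) N
    masses: np.ndarray          # (N,) kg
    densities: np.ndarray       # (N,) kg m^-3
    phase: np.ndarray           # (N,) int8, Phase values
    slice_index: np.ndarray     # (N,) int32, -1 for fluid
    winding: np.ndarray = field(default=None)  # (N,) int64

    def __post_init__(self) -> None:
        n = len(self.positions)
        if self.winding is None:
            self.winding = np.zeros(n, dtype=np.int64)
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.forces = np.ascontiguousarray(self.forces, dtype=np.float64)
        self.masses = np.ascontiguousarray(self.masses, dtype=np.float64)
        self.densities = np.ascontiguousarray(self.densities, dtype=np.float64)
        self.phase = np.ascontiguousarray(self.phase, dtype=np.int8)
        self.slice_index = np.ascontiguousarray(self.slice_index, dtype=np.int32)
        self.winding = np.ascontiguousarray(self.winding, dtype=np.int64)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.phase == Phase.FLUID

    @property
    def solid_mask(self) -> np.ndarray:
        return self.phase == Phase.SOLID

    def validate(self) -> None:
        n = self.n
        for name in ("velocities", "forces"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
        for name in ("masses", "densities", "phase", "slice_index", "winding"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if np.any(self.masses <= 0):
            raise ValueError("all particle masses must be positive")
        solid = self.solid_mask
        if np.any(self.slice_index[solid] < 0):
            raise ValueError("solid particles must carry a slice index")
        if np.any(self.slice_index[~solid] != -1):
            raise ValueError("fluid particles must have slice_index -1")

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            forces=self.forces.copy(),
            masses=self.masses.copy(),
            densities=self.densities.copy(),
            phase=self.phase.copy(),
            slice_index=self.slice_index.copy(),
            winding=self.winding.copy(),
        )


@dataclass(frozen=True)
class BoxGeometry:
    """Periodic box: periodic along the tube axis (x) only."""

    axial_length: float                  # m, periodic period L
    transverse_extent: float = np.inf    # m, informational only

    def __post_init__(self) -> None:
        if not self.axial_length > 0:
            raise ValueError("axial_length must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and numerical constants of the tube model (SI units).

    Defaults are the published parameter set of the intestine analogue:
    time step 1 ms, smoothing length 9 mm, membrane spring constant
    9e-2 N/m with 6 mm equilibrium spacing, tether stiffness 5e-4 N/m,
    contraction force 4e-4 N and repulsion barrier 2e-6 J.  The reference
    sound speed c0 is not part of the published set; the default keeps the
    flow comfortably in the weakly-compressible regime (flow speeds here
    are ~1 cm/s).  The viscous coefficient ``a`` maps the physical
    kinematic viscosity (1e-4 m^2/s, i.e. 0.1 Pa s at 1000 kg/m^3) through
    :func:`viscosity_coefficient`.
    """

    dt: float = 1.0e-3            # s
    c0: float = 1.0               # m s^-1 reference sound speed
    rho0: float = 1000.0          # kg m^-3 reference density
    h: float = 9.0e-3             # m smoothing length
    a: float = 10.0 * 1.0e-4 / (9.0e-3 * 1.0)   # dimensionless, see viscosity_coefficient
    b: float = 0.01               # dimensionless stabiliser
    k: float = 9.0e-2             # N m^-1 membrane bond stiffness
    k_tether: float = 5.0e-4      # N m^-1 tether stiffness
    r0_bond: float = 6.0e-3       # m membrane equilibrium spacing
    f0: float = 4.0e-4            # N contraction force magnitude
    A_repulsive: float = 2.0e-6   # J interface repulsion barrier
    r0_repulsive: float = 6.0e-3  # m interface repulsion range
    tait_prefactor_mode: str = "squared"   # "squared" | "as_printed"

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.h > 0:
            raise ValueError("h must be positive")
        if not self.b > 0:
            raise ValueError("b must be positive")
        for name in ("k", "k_tether", "f0", "A_repulsive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tait_prefactor_mode not in ("squared", "as_printed"):
            raise ValueError("tait_prefactor_mode must be 'squared' or 'as_printed'")

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def viscosity_coefficient(nu: float, h: float, c0: float, dim: int = 3) -> float:
    """Pair-viscosity coefficient ``a`` reproducing kinematic viscosity ``nu``.

    Uses the standard correspondence nu_eff ~ a*h*c0 / (2*(dim+2)) between
    the Monaghan-type pair term and a Navier-Stokes shear viscosity.
    """
    return 2.0 * (dim + 2) * nu / (h * c0)


# ---------------------------------------------------------------------------
# neighbour search


@njit(cache=True)
def _count_fill_pairs(pos, L, cutoff, order, bin_start, bin_count, nbins,
                      pi, pj, pr, pdx, pdy, pdz, fill):
    cut2 = cutoff * cutoff
    m = 0
    for b in range(nbins):
        for db in range(2):           # own bin, then next bin (periodic)
            nb = (b + db) % nbins
            if db == 1 and nb == b:
                continue
            for ii in range(bin_start[b], bin_start[b] + bin_count[b]):
                i = order[ii]
                start_j = ii + 1 if db == 0 else bin_start[nb]
                end_j = bin_start[b] + bin_count[b] if db == 0 else bin_start[nb] + bin_count[nb]
                for jj in range(start_j, end_j):
                    j = order[jj]
                    dx = pos[i, 0] - pos[j, 0]
                    if dx > 0.5 * L:
                        dx -= L
                    elif dx < -0.5 * L:
                        dx += L
                    dy = pos[i, 1] - pos[j, 1]
                    dz = pos[i, 2] - pos[j, 2]
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 < cut2:
                        if fill:
                            pi[m] = i
                            pj[m] = j
                            pr[m] = np.sqrt(d2)
                            pdx[m] = dx
                            pdy[m] = dy
                            pdz[m] = dz
                        m += 1
    return m


@njit(cache=True)
def _brute_pairs(pos, L, cutoff, pi, pj, pr, pdx, pdy, pdz, fill):
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            if dx > 0.5 * L:
                dx -= L
            elif dx < -0.5 * L:
                dx += L
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < cut2:
                if fill:
                    pi[m] = i
                    pj[m] = j
                    pr[m] = np.sqrt(d2)
                    pdx[m] = dx
                    pdy[m] = dy
                    pdz[m] = dz
                m += 1
    return m


@dataclass
class PairList:
    """Unordered particle pairs within a cutoff, minimum-imaged along x.

    ``disp`` holds r_i - r_j (minimum image); ``dist`` its norm.
    """

    i: np.ndarray
    j: np.ndarray
    dist: np.ndarray
    disp: np.ndarray  # (M, 3)

    @property
    def m(self) -> int:
        return len(self.i)


def build_neighbor_list(system: ParticleSystem, box: BoxGeometry,
                        cutoff: float) -> PairList:
    """All unordered pairs with minimum-image distance < cutoff.

    Linked-cell binning along the periodic axis when the box admits at
    least three cells; otherwise an exhaustive scan (equivalent result).
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    L = box.axial_length
    if cutoff > 0.5 * L:
        raise ValueError(
            f"cutoff {cutoff} exceeds half the axial period {L}: "
            "minimum-image convention is ambiguous"
        )
    pos = system.positions
    n = system.n
    nbins = int(L // cutoff)
    empty_i = np.empty(0, dtype=np.int64)
    empty_f = np.empty(0, dtype=np.float64)
    if nbins >= 3:
        width = L / nbins
        bins = np.minimum((np.mod(pos[:, 0], L) // width).astype(np.int64), nbins - 1)
        order = np.argsort(bins, kind="stable")
        bin_count = np.bincount(bins, minlength=nbins)
        bin_start = np.concatenate(([0], np.cumsum(bin_count)[:-1]))
        m = _count_fill_pairs(pos, L, cutoff, order, bin_start, bin_count, nbins,
                              empty_i, empty_i, empty_f, empty_f, empty_f, empty_f, False)
        pi = np.empty(m, dtype=np.int64)
        pj = np.empty(m, dtype=np.int64)
        pr = np.empty(m, dtype=np.float64)
        pdx = np.empty(m, dtype=np.float64)
        pdy = np.empty(m, dtype=np.float64)
        pdz = np.empty(m, dtype=np.float64)
        _count_fill_pairs(pos, L, cutoff, order, bin_start, bin_count, nbins,
                          pi, pj, pr, pdx, pdy, pdz, True)
    else:
        m = _brute_pairs(pos, L, cutoff, empty_i, empty_i, empty_f,
                         empty_f, empty_f, empty_f, False)
        pi = np.empty(m, dtype=np.int64)
        pj = np.empty(m, dtype=np.int64)
        pr = np.empty(m, dtype=np.float64)
        pdx = np.empty(m, dtype=np.float64)
        pdy = np.empty(m, dtype=np.float64)
        pdz = np.empty(m, dtype=np.float64)
        _brute_pairs(pos, L, cutoff, pi, pj, pr, pdx, pdy, pdz, True)
    disp = np.stack((pdx, pdy, pdz), axis=1) if m else np.empty((0, 3))
    return PairList(i=pi, j=pj, dist=pr, disp=disp)


# ---------------------------------------------------------------------------
# periodic wrapping


def wrap_positions(system: ParticleSystem, box: BoxGeometry) -> ParticleSystem:
    """Fold axial coordinates into [0, L), updating winding counts in place.

    Idempotent; the unwrapped coordinate x + winding*L is preserved.
    """
    L = box.axial_length
    x = system.positions[:, 0]
    crossings = np.floor(x / L).astype(np.int64)
    wrapped = x - crossings * L
    # floating-point guard: x just below a multiple of L can round to L
    on_edge = wrapped >= L
    wrapped[on_edge] -= L
    crossings[on_edge] += 1
    system.winding += crossings
    system.positions[:, 0] = wrapped
    return system


def unwrapped_axial(system: ParticleSystem, box: BoxGeometry) -> np.ndarray:
    """Continuous (winding-corrected) axial coordinates."""
    return system.positions[:, 0] + system.winding * box.axial_length


# ---------------------------------------------------------------------------
# time integration


ForceCallback = Callable[[ParticleSystem], np.ndarray]


def _check_finite_forces(forces: np.ndarray) -> None:
    bad = ~np.isfinite(forces).all(axis=1)
    if bad.any():
        idx = int(np.nonzero(bad)[0][0])
        raise FloatingPointError(f"non-finite force on particle {idx}")


def integrate_step(system: ParticleSystem, box: BoxGeometry,
                   force_callback: ForceCallback, dt: float) -> ParticleSystem:
    """Advance one velocity-Verlet step.

    ``system.forces`` must hold the forces at the current positions on
    entry (call the callback once before the first step); on exit it holds
    the forces at the new positions.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    _check_finite_forces(system.forces)
    inv_m = 1.0 / system.masses[:, None]
    system.velocities += 0.5 * dt * system.forces * inv_m
    system.positions += dt * system.velocities
    wrap_positions(system, box)
    new_forces = force_callback(system)
    _check_finite_forces(new_forces)
    system.forces = np.ascontiguousarray(new_forces, dtype=np.float64)
    system.velocities += 0.5 * dt * system.forces * inv_m
    return system
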