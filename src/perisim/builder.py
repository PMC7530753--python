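"""Programmatic construction of the fluid-filled contractile tube.

The geometry is a cylinder of length L (periodic axis x) and diameter D.
Fluid particles sit on concentric rings repeated along the axis; membrane
particles form rings on the cylinder surface, bonded to their lattice
neighbours and tethered to their build positions.  The membrane is
partitioned axially into ``n_slices`` equal sections (default 10) — the
units of contraction and the state/action alphabet of the learning agent.

The ``full`` preset reproduces the published particle budget exactly:
12,078 fluid + 2,500 membrane = 14,578 particles (671 axial fluid layers
of 18 particles; 500 membrane rings of 5).  The published counts fix the
totals but not the ring decomposition, so the decomposition used here is
a reconstruction.  Reduced presets (``desk3d``, ``tiny``) shorten the
tube and coarsen the lattice for desk-scale runs while keeping every
physical constant unchanged.

Particle mass: the reduced presets calibrate the (common) particle mass
so that the initial SPH summation density averages rho0 — the consistent
choice when density is evaluated by summation in a tube narrower than
the smoothing kernel.  The ``full`` preset keeps the published mass of
2.5e-4 kg per particle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .core import BoxGeometry, ParticleSystem, Phase, SimulationConfig, build_neighbor_list
from .membrane import BondTable, TetherSet
from .sph import compute_density

__all__ = [
    "TubeGeometry",
    "TubeModel",
    "assign_slices",
    "build_tube",
    "get_preset",
    "PRESETS",
    "build_channel",
]


@dataclass(frozen=True)
class TubeGeometry:
    """Construction parameters of the tube lattice (SI units)."""

    length: float = 0.6
    diameter: float = 5.0e-3
    n_axial_fluid: int = 671
    #: concentric fluid rings per axial layer: (count, radius fraction of
    #: the fluid radius); count 1 means an on-axis particle.
    fluid_rings: tuple = ((6, 0.45), (12, 0.85))
    fluid_radius_fraction: float = 0.8   # fluid radius / membrane radius
    n_rings_solid: int = 500
    per_ring_solid: int = 5
    n_slices: int = 10
    particle_mass: float = 2.5e-4        # kg, used when calibrate_mass=False
    calibrate_mass: bool = False
    relax_steps: int = 0                 # build-time settling steps
    relax_damping: float = 0.05
    #: interface repulsion range override; None keeps the config value.
    #: The presets set it to the fluid lattice contact scale so the
    #: barrier acts at the wall, not across the whole lumen.
    repulsion_range: float | None = None

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_rings_solid % self.n_slices:
            raise ValueError("membrane rings must tile the slices evenly")

    @property
    def n_fluid(self) -> int:
        return self.n_axial_fluid * sum(c for c, _ in self.fluid_rings)

    @property
    def n_solid(self) -> int:
        return self.n_rings_solid * self.per_ring_solid

    @property
    def lattice_spacing(self) -> float:
        """Axial fluid layer spacing — the reference lattice scale."""
        return self.length / self.n_axial_fluid

    @property
    def slice_thickness(self) -> float:
        return self.length / self.n_slices


@dataclass
class TubeModel:
    """Built tube: particle state plus bonds, tethers and geometry.

    ``initial`` is a pristine copy of the settled build state; episode
    resets and the rest slice radii reference it.
    """

    system: ParticleSystem
    bonds: BondTable
    tethers: TetherSet
    geometry: TubeGeometry
    box: BoxGeometry
    config: SimulationConfig
    initial: ParticleSystem = field(default=None)

    def __post_init__(self) -> None:
        if self.initial is None:
            self.initial = self.system.copy()

    def reset(self) -> None:
        self.system = self.initial.copy()

    @property
    def fluid_volume(self) -> float:
        """Rest lumen volume, pi * mean(rest membrane radius)^2 * L.

        The geometric volume enclosed by the settled membrane; used for
        the plug-flow equivalence in the dimensionless cumulative reward
        (consistent with the slice-volume estimate used for the squeezed
        volume, which is also based on mean membrane radii).
        """
        radii = self.slice_mean_radii(self.initial)
        return float(np.pi * np.mean(radii ** 2) * self.geometry.length)

    def slice_mean_radii(self, system: ParticleSystem | None = None) -> np.ndarray:
        """Mean membrane radius per slice (length n_slices)."""
        sys_ = self.system if system is None else system
        sol = sys_.solid_mask
        r = np.sqrt(sys_.positions[sol, 1] ** 2 + sys_.positions[sol, 2] ** 2)
        idx = sys_.slice_index[sol]
        out = np.zeros(self.geometry.n_slices)
        for s in range(self.geometry.n_slices):
            out[s] = r[idx == s].mean()
        return out


def assign_slices(axial: np.ndarray, length: float, n_slices: int) -> np.ndarray:
    """Slice index floor(x / (L/n_slices)), clamped to n_slices - 1."""
    axial = np.asarray(axial, dtype=np.float64)
    idx = np.floor(axial / (length / n_slices)).astype(np.int32)
    return np.clip(idx, 0, n_slices - 1)


def _ring(n: int, radius: float, phase_angle: float = 0.0) -> np.ndarray:
    ang = phase_angle + 2.0 * np.pi * np.arange(n) / n
    return np.stack((radius * np.cos(ang), radius * np.sin(ang)), axis=1)


def _fluid_positions(geom: TubeGeometry) -> np.ndarray:
    rf = geom.fluid_radius_fraction * 0.5 * geom.diameter
    cross = []
    for count, frac in geom.fluid_rings:
        if count == 1:
            cross.append(np.zeros((1, 2)))
        else:
            cross.append(_ring(count, frac * rf))
    cross = np.concatenate(cross, axis=0)
    xs = (np.arange(geom.n_axial_fluid) + 0.5) * geom.length / geom.n_axial_fluid
    pos = np.empty((geom.n_fluid, 3))
    k = cross.shape[0]
    for layer, x in enumerate(xs):
        pos[layer * k:(layer + 1) * k, 0] = x
        pos[layer * k:(layer + 1) * k, 1:] = cross
    return pos


def _solid_positions(geom: TubeGeometry) -> np.ndarray:
    radius = 0.5 * geom.diameter
    xs = (np.arange(geom.n_rings_solid) + 0.5) * geom.length / geom.n_rings_solid
    pos = np.empty((geom.n_solid, 3))
    for ring_idx, x in enumerate(xs):
        # alternate rings staggered by half an angular step
        phase_angle = (ring_idx % 2) * np.pi / geom.per_ring_solid
        ring = _ring(geom.per_ring_solid, radius, phase_angle)
        lo = ring_idx * geom.per_ring_solid
        pos[lo:lo + geom.per_ring_solid, 0] = x
        pos[lo:lo + geom.per_ring_solid, 1:] = ring
    return pos


def _membrane_bond_cutoff(geom: TubeGeometry) -> float:
    radius = 0.5 * geom.diameter
    chord = 2.0 * radius * np.sin(np.pi / geom.per_ring_solid)
    half_chord = 2.0 * radius * np.sin(0.5 * np.pi / geom.per_ring_solid)
    s_ax = geom.length / geom.n_rings_solid
    inter_ring = np.hypot(s_ax, half_chord)
    return 1.1 * max(chord, inter_ring)


def build_tube(geometry: TubeGeometry,
               config: SimulationConfig | None = None) -> TubeModel:
    """Deterministically place particles, bonds and tethers.

    No randomness anywhere: repeated builds are bit-identical.  When
    ``geometry.relax_steps > 0`` the assembled system is settled with
    damped dynamics so that the stored initial state is close to force
    balance; tether anchors stay at the as-placed lattice positions.
    """
    from .forces import run_steps  # local import to avoid a cycle

    config = config or SimulationConfig()
    if geometry.repulsion_range is not None:
        config = config.with_overrides(r0_repulsive=geometry.repulsion_range)
    fluid_pos = _fluid_positions(geometry)
    solid_pos = _solid_positions(geometry)
    n_f, n_s = len(fluid_pos), len(solid_pos)
    if n_s == 0:
        raise ValueError("geometry places no membrane rings")
    n = n_f + n_s
    positions = np.concatenate((fluid_pos, solid_pos), axis=0)
    phase = np.concatenate((np.full(n_f, Phase.FLUID, dtype=np.int8),
                            np.full(n_s, Phase.SOLID, dtype=np.int8)))
    slice_index = np.full(n, -1, dtype=np.int32)
    slice_index[n_f:] = assign_slices(solid_pos[:, 0], geometry.length,
                                      geometry.n_slices)
    box = BoxGeometry(axial_length=geometry.length,
                      transverse_extent=geometry.diameter)
    system = ParticleSystem(
        positions=positions,
        velocities=np.zeros((n, 3)),
        forces=np.zeros((n, 3)),
        masses=np.ones(n),
        densities=np.full(n, config.rho0),
        phase=phase,
        slice_index=slice_index,
    )
    if geometry.calibrate_mass:
        # unit-mass summation gives the kernel sum; scale so <rho> = rho0
        compute_density(system, box, config.h, rho_solid=config.rho0)
        kernel_sum = system.densities[system.fluid_mask].mean()
        mass = config.rho0 / kernel_sum
    else:
        mass = geometry.particle_mass
    system.masses[:] = mass
    compute_density(system, box, config.h, rho_solid=config.rho0)

    # membrane bonds: lattice neighbours of the as-built wall
    solid_only = ParticleSystem(
        positions=solid_pos.copy(),
        velocities=np.zeros((n_s, 3)),
        forces=np.zeros((n_s, 3)),
        masses=np.full(n_s, mass),
        densities=np.full(n_s, config.rho0),
        phase=np.full(n_s, Phase.SOLID, dtype=np.int8),
        slice_index=slice_index[n_f:].copy(),
    )
    pairs = build_neighbor_list(solid_only, box, _membrane_bond_cutoff(geometry))
    bonds = BondTable(i=pairs.i + n_f, j=pairs.j + n_f,
                      rest_length=pairs.dist.copy(), k=config.k)
    anchors = np.full((n, 3), np.nan)
    anchors[n_f:] = solid_pos
    tethers = TetherSet(anchors=anchors, k_tether=config.k_tether)

    model = TubeModel(system=system, bonds=bonds, tethers=tethers,
                      geometry=geometry, box=box, config=config)
    if geometry.relax_steps > 0:
        run_steps(model.system, box, config, bonds, tethers,
                  geometry.relax_steps,
                  velocity_damping=geometry.relax_damping)
        model.system.velocities[:] = 0.0
        model.system.winding[:] = 0
        model.initial = model.system.copy()
    return model


PRESETS = {
    # published scale: 12,078 fluid + 2,500 membrane = 14,578 particles
    "full": TubeGeometry(repulsion_range=0.9e-3),
    # ~10x shorter tube, same diameter and constants, <= 1,500 particles
    "desk3d": TubeGeometry(length=0.06, n_axial_fluid=67,
                           n_rings_solid=50, calibrate_mass=True,
                           relax_steps=1000, repulsion_range=0.9e-3),
    # minimal desk model, <= 300 particles
    "tiny": TubeGeometry(length=0.06, n_axial_fluid=40,
                         fluid_rings=((1, 0.0), (4, 0.6)),
                         n_rings_solid=20, calibrate_mass=True,
                         relax_steps=400, repulsion_range=1.5e-3),
}


def get_preset(name: str) -> TubeGeometry:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")


def geometry_to_dict(geom: TubeGeometry) -> dict:
    d = asdict(geom)
    d["fluid_rings"] = [list(r) for r in geom.fluid_rings]
    return d


def geometry_from_dict(d: dict) -> TubeGeometry:
    d = dict(d)
    d["fluid_rings"] = tuple(tuple(r) for r in d["fluid_rings"])
    return TubeGeometry(**d)


def build_channel(n_axial: int = 80, n_across: int = 9, spacing: float = 1e-3,
                  wall_layers: int = 1,
                  config: SimulationConfig | None = None) -> TubeModel:
    """Small planar channel: fluid sheet between two tethered walls.

    A validation geometry for the no-slip coupling: driving the fluid
    axially should develop a sheared profile that vanishes near the
    walls.  Reuses the tube containers with a single slice.  The default
    config uses a contact-scale repulsion range (one lattice spacing,
    equal to the built wall-fluid gap), as the tube presets do.
    """
    config = config or SimulationConfig(r0_repulsive=spacing)
    L = n_axial * spacing
    ys = (np.arange(n_across) - (n_across - 1) / 2) * spacing
    xs = (np.arange(n_axial) + 0.5) * spacing
    fluid = np.array([(x, y, 0.0) for x in xs for y in ys])
    gap = 0.5 * (n_across + 1) * spacing
    wall_rows = []
    for layer in range(wall_layers):
        off = gap + layer * spacing
        for x in xs:
            wall_rows.append((x, off, 0.0))
            wall_rows.append((x, -off, 0.0))
    solid = np.array(wall_rows)
    n_f, n_s = len(fluid), len(solid)
    n = n_f + n_s
    positions = np.concatenate((fluid, solid))
    phase = np.concatenate((np.full(n_f, Phase.FLUID, dtype=np.int8),
                            np.full(n_s, Phase.SOLID, dtype=np.int8)))
    slice_index = np.full(n, -1, dtype=np.int32)
    slice_index[n_f:] = 0
    box = BoxGeometry(axial_length=L)
    system = ParticleSystem(
        positions=positions, velocities=np.zeros((n, 3)),
        forces=np.zeros((n, 3)), masses=np.ones(n),
        densities=np.full(n, config.rho0), phase=phase,
        slice_index=slice_index)
    compute_density(system, box, config.h, rho_solid=config.rho0)
    kernel_sum = system.densities[system.fluid_mask].mean()
    system.masses[:] = config.rho0 / kernel_sum
    compute_density(system, box, config.h, rho_solid=config.rho0)
    bonds = BondTable(i=np.empty(0, dtype=np.int64),
                      j=np.empty(0, dtype=np.int64),
                      rest_length=np.empty(0), k=config.k)
    anchors = np.full((n, 3), np.nan)
    anchors[n_f:] = solid
    tethers = TetherSet(anchors=anchors, k_tether=max(config.k_tether, 1.0))
    geom = TubeGeometry(length=L, diameter=2 * gap, n_axial_fluid=n_axial,
                        fluid_rings=((n_across, 0.0),),
                        n_rings_solid=1, per_ring_solid=n_s, n_slices=1,
                        particle_mass=float(system.masses[0]))
    return TubeModel(system=system, bonds=bonds, tethers=tethers,
                     geometry=geom, box=box, config=config)
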