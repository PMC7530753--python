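"""Weakly-compressible SPH: kernel, summation density, Tait pressure and
pairwise pressure/viscous forces for the luminal fluid.

The equation of state is the Tait relation

    P = (c0^2 rho0 / 7) [ (rho/rho0)^7 - 1 ]

which enforces weak compressibility: density excursions of ~1% produce
pressures large enough to resist further compression.  The printed form of
the prefactor in the source material, c0*rho0/7, is not dimensionally a
pressure; the standard c0^2 form is the default and the literal form
remains selectable via ``tait_prefactor_mode='as_printed'``.

Viscosity acts through the Monaghan-type pair term

    Pi_ij = -a h (c0 / rho_ij) (v_ij . r_ij) / (|r_ij|^2 + b h^2)

with rho_ij = rho_i + rho_j (a sum, not a mean) and v_ij = v_i - v_j.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import BoxGeometry, PairList, ParticleSystem, Phase, SimulationConfig, build_neighbor_list

__all__ = [
    "SUPPORT_FACTOR",
    "kernel",
    "kernel_gradient",
    "compute_density",
    "tait_pressure",
    "density_from_pressure",
    "viscous_term",
    "fluid_pair_forces",
]

#: kernel support radius in units of h (cubic spline)
SUPPORT_FACTOR = 2.0


@njit(cache=True)
def _w_cubic(r: float, h: float) -> float:
    sigma = 1.0 / (np.pi * h ** 3)
    q = r / h
    if q < 1.0:
        return sigma * (1.0 - 1.5 * q * q + 0.75 * q * q * q)
    elif q < 2.0:
        t = 2.0 - q
        return sigma * 0.25 * t * t * t
    return 0.0


@njit(cache=True)
def _dwdr_cubic(r: float, h: float) -> float:
    sigma = 1.0 / (np.pi * h ** 3)
    q = r / h
    if q < 1.0:
        return sigma * (-3.0 * q + 2.25 * q * q) / h
    elif q < 2.0:
        t = 2.0 - q
        return -sigma * 0.75 * t * t / h
    return 0.0


def kernel(r, h: float):
    """Cubic-spline kernel W(r, h), support radius 2h, normalised in 3D."""
    if not h > 0:
        raise ValueError("smoothing length h must be positive")
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    out = np.vectorize(_w_cubic)(r, h)
    return float(out) if out.ndim == 0 else out


def kernel_gradient(r: float, e_ij: np.ndarray, h: float) -> np.ndarray:
    """Gradient of W with respect to particle i: dW/dr * e_ij.

    ``e_ij`` is the unit vector from j to i, so the gradient is
    antisymmetric under exchange of the pair.
    """
    if not h > 0:
        raise ValueError("smoothing length h must be positive")
    return _dwdr_cubic(float(r), h) * np.asarray(e_ij, dtype=np.float64)


@njit(cache=True)
def _density_sum(n, pair_i, pair_j, pair_r, masses, is_fluid, h):
    rho = np.zeros(n)
    for i in range(n):
        if is_fluid[i]:
            rho[i] = masses[i] * _w_cubic(0.0, h)
    for m in range(len(pair_i)):
        i = pair_i[m]
        j = pair_j[m]
        if is_fluid[i] and is_fluid[j]:
            w = _w_cubic(pair_r[m], h)
            rho[i] += masses[j] * w
            rho[j] += masses[i] * w
    return rho


def compute_density(system: ParticleSystem, box: BoxGeometry, h: float,
                    pairs: PairList | None = None,
                    rho_solid: float | None = None) -> np.ndarray:
    """Summation density for fluid particles, rho_i = sum_j m_j W(r_ij, h).

    The sum runs over fluid neighbours (membrane particles carry no SPH
    mass distribution) and includes the self term.  Solid particles are
    assigned the constant ``rho_solid`` (reference density) if given,
    otherwise their stored density is left untouched.  Updates
    ``system.densities`` in place and returns it.
    """
    if pairs is None:
        pairs = build_neighbor_list(system, box, SUPPORT_FACTOR * h)
    is_fluid = system.phase == Phase.FLUID
    rho = _density_sum(system.n, pairs.i, pairs.j, pairs.dist,
                       system.masses, is_fluid, h)
    if rho_solid is not None:
        rho[~is_fluid] = rho_solid
    else:
        rho[~is_fluid] = system.densities[~is_fluid]
    system.densities = rho
    return rho


def tait_pressure(rho, c0: float, rho0: float, mode: str = "squared"):
    """Tait equation of state; monotone in rho with P(rho0) = 0."""
    rho = np.asarray(rho, dtype=np.float64)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    if mode == "squared":
        pref = c0 * c0 * rho0 / 7.0
    elif mode == "as_printed":
        pref = c0 * rho0 / 7.0
    else:
        raise ValueError("mode must be 'squared' or 'as_printed'")
    out = pref * ((rho / rho0) ** 7 - 1.0)
    return float(out) if out.ndim == 0 else out


def density_from_pressure(p: float, c0: float, rho0: float,
                          mode: str = "squared") -> float:
    """Invert the Tait relation (strictly increasing, hence unique)."""
    if mode == "squared":
        pref = c0 * c0 * rho0 / 7.0
    else:
        pref = c0 * rho0 / 7.0
    return rho0 * (p / pref + 1.0) ** (1.0 / 7.0)


def viscous_term(v_ij: np.ndarray, r_vec: np.ndarray, rho_ij: float,
                 a: float, b: float, h: float, c0: float) -> float:
    """Monaghan pair-viscosity scalar Pi_ij.

    Symmetric under exchange of i and j (both v_ij and r_vec flip sign).
    Positive when the pair approaches (v_ij . r_vec < 0), which enters the
    momentum equation as a repulsive, dissipative contribution.
    """
    v_ij = np.asarray(v_ij, dtype=np.float64)
    r_vec = np.asarray(r_vec, dtype=np.float64)
    r2 = float(np.dot(r_vec, r_vec))
    if not r2 > 0:
        raise ValueError("pair distance must be positive")
    return -a * h * (c0 / rho_ij) * float(np.dot(v_ij, r_vec)) / (r2 + b * h * h)


@njit(cache=True)
def _fluid_forces_kernel(n, pair_i, pair_j, pair_r, disp, vel, masses, rho,
                         press, is_fluid, a, b, h, c0):
    forces = np.zeros((n, 3))
    bh2 = b * h * h
    for m in range(len(pair_i)):
        i = pair_i[m]
        j = pair_j[m]
        if not (is_fluid[i] and is_fluid[j]):
            continue
        r = pair_r[m]
        if r <= 0.0:
            return forces, m  # overlapping pair: flag for the caller
        dwdr = _dwdr_cubic(r, h)
        if dwdr == 0.0:
            continue
        dx = disp[m, 0]
        dy = disp[m, 1]
        dz = disp[m, 2]
        vx = vel[i, 0] - vel[j, 0]
        vy = vel[i, 1] - vel[j, 1]
        vz = vel[i, 2] - vel[j, 2]
        vdotr = vx * dx + vy * dy + vz * dz
        rho_ij = rho[i] + rho[j]
        pi_ij = -a * h * (c0 / rho_ij) * vdotr / (r * r + bh2)
        coef = -masses[i] * masses[j] * (
            press[i] / (rho[i] * rho[i]) + press[j] / (rho[j] * rho[j]) + pi_ij
        ) * dwdr / r
        fx = coef * dx
        fy = coef * dy
        fz = coef * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return forces, -1


def fluid_pair_forces(system: ParticleSystem, box: BoxGeometry,
                      config: SimulationConfig,
                      pairs: PairList | None = None) -> np.ndarray:
    """Pressure + viscous forces between fluid pairs.

    F_i = -sum_j m_i m_j (P_i/rho_i^2 + P_j/rho_j^2 + Pi_ij) grad_i W;
    pairwise antisymmetric, hence exactly momentum conserving.  Densities
    must be current (call :func:`compute_density` first).
    """
    if pairs is None:
        pairs = build_neighbor_list(system, box, SUPPORT_FACTOR * config.h)
    is_fluid = system.phase == Phase.FLUID
    press = np.zeros(system.n)
    press[is_fluid] = tait_pressure(system.densities[is_fluid], config.c0,
                                    config.rho0, config.tait_prefactor_mode)
    forces, bad = _fluid_forces_kernel(
        system.n, pairs.i, pairs.j, pairs.dist, pairs.disp,
        system.velocities, system.masses, system.densities, press,
        is_fluid, config.a, config.b, config.h, config.c0)
    if bad >= 0:
        raise ValueError(
            f"overlapping fluid particles {pairs.i[bad]} and {pairs.j[bad]}"
        )
    return forces
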