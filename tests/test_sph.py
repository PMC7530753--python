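"""SPH kernel, summation density, Tait pressure and fluid pair forces."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from perisim.core import BoxGeometry, Phase, SimulationConfig, build_neighbor_list
from perisim.sph import (SUPPORT_FACTOR, compute_density, density_from_pressure,
                         fluid_pair_forces, kernel, kernel_gradient,
                         tait_pressure, viscous_term)
from helpers import make_system


class TestKernel:
    def test_compact_support(self):
        h = 9e-3
        assert kernel(SUPPORT_FACTOR * h, h) == 0.0
        assert kernel(3 * h, h) == 0.0
        np.testing.assert_array_equal(kernel_gradient(2.5 * h, np.array([1, 0, 0]), h),
                                      np.zeros(3))

    def test_maximal_at_origin_and_monotone(self):
        h = 9e-3
        rs = np.linspace(0, 2 * h, 200)
        ws = kernel(rs, h)
        assert np.all(ws >= 0)
        assert np.all(np.diff(ws) <= 1e-15)
        assert ws[0] == max(ws)

    def test_normalised_by_quadrature(self):
        h = 9e-3
        integral, _ = quad(lambda r: kernel(r, h) * 4 * np.pi * r ** 2,
                           0, SUPPORT_FACTOR * h, limit=200)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_gradient_antisymmetric_under_exchange(self):
        h = 9e-3
        e = np.array([0.6, 0.8, 0.0])
        g_ij = kernel_gradient(4e-3, e, h)
        g_ji = kernel_gradient(4e-3, -e, h)
        np.testing.assert_allclose(g_ij, -g_ji, rtol=1e-14)

    def test_invalid_h_rejected(self):
        with pytest.raises(ValueError):
            kernel(1e-3, 0.0)


class TestDensity:
    def test_isolated_particle_self_term(self):
        h = 9e-3
        sys_ = make_system([[0.5, 0, 0]], masses=np.array([2.0]))
        rho = compute_density(sys_, BoxGeometry(1.0), h)
        assert rho[0] == pytest.approx(2.0 * kernel(0.0, h), rel=1e-12)

    def test_uniform_lattice_recovers_reference_density(self):
        """Interior summation densities on a cubic lattice sized for
        rho0 = 1000 are within 3% of rho0."""
        s = 1e-3
        rho0 = 1000.0
        h = 1.3 * s
        n = 10
        grid = (np.mgrid[0:n, 0:n, 0:n].reshape(3, -1).T + 0.5) * s
        sys_ = make_system(grid, masses=np.full(n ** 3, rho0 * s ** 3))
        rho = compute_density(sys_, BoxGeometry(n * s), h)
        # periodic along x; pick particles away from the open y/z faces
        margin = SUPPORT_FACTOR * h
        interior = ((grid[:, 1] > margin) & (grid[:, 1] < n * s - margin)
                    & (grid[:, 2] > margin) & (grid[:, 2] < n * s - margin))
        assert interior.sum() > 100
        np.testing.assert_allclose(rho[interior], rho0, rtol=0.03)

    def test_mirror_symmetry(self, rng):
        h = 9e-3
        pos = rng.uniform([0.2, -0.01, -0.01], [0.8, 0.01, 0.01], (30, 3))
        box = BoxGeometry(1.0)
        a = make_system(pos.copy())
        mirrored = pos.copy()
        mirrored[:, 1] *= -1
        b = make_system(mirrored)
        rho_a = compute_density(a, box, h)
        rho_b = compute_density(b, box, h)
        np.testing.assert_allclose(np.sort(rho_a), np.sort(rho_b), rtol=1e-12)


class TestTait:
    def test_zero_at_reference_density(self):
        assert tait_pressure(1000.0, 10.0, 1000.0) == 0.0

    def test_printed_value_one_percent_compression(self):
        p = tait_pressure(1010.0, 10.0, 1000.0, mode="squared")
        expected = (10.0 ** 2 * 1000.0 / 7.0) * (1.01 ** 7 - 1.0)
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(1.0305e3, rel=1e-3)

    def test_as_printed_mode_scales_by_c0(self):
        p_sq = tait_pressure(1010.0, 10.0, 1000.0, mode="squared")
        p_lit = tait_pressure(1010.0, 10.0, 1000.0, mode="as_printed")
        assert p_lit == pytest.approx(p_sq / 10.0, rel=1e-12)

    def test_tension_below_reference(self):
        assert tait_pressure(990.0, 10.0, 1000.0) < 0.0

    @given(st.floats(500.0, 2000.0), st.floats(500.0, 2000.0))
    def test_strictly_monotone_and_invertible(self, rho_a, rho_b):
        c0, rho0 = 5.0, 1000.0
        pa = tait_pressure(rho_a, c0, rho0)
        pb = tait_pressure(rho_b, c0, rho0)
        if rho_a < rho_b:
            assert pa < pb
        rho_back = density_from_pressure(pa, c0, rho0)
        assert rho_back == pytest.approx(rho_a, rel=1e-10)


class TestViscousTerm:
    def test_zero_for_comoving_pair(self):
        assert viscous_term(np.zeros(3), np.array([1e-3, 0, 0]), 2000.0,
                            a=1.0, b=0.01, h=9e-3, c0=10.0) == 0.0

    def test_symmetric_under_exchange(self):
        v = np.array([0.01, -0.02, 0.005])
        r = np.array([3e-3, 1e-3, -2e-3])
        args = dict(rho_ij=2000.0, a=0.5, b=0.01, h=9e-3, c0=10.0)
        assert viscous_term(v, r, **args) == pytest.approx(
            viscous_term(-v, -r, **args), rel=1e-14)

    def test_printed_arithmetic(self):
        # v.r = -1e-4 realised as v = (-0.02, 0, 0), r = (5e-3, 0, 0)
        v = np.array([-0.02, 0.0, 0.0])
        r = np.array([5e-3, 0.0, 0.0])
        a, h, c0, rho_ij, b = 1.0, 9e-3, 10.0, 2000.0, 0.01
        got = viscous_term(v, r, rho_ij, a, b, h, c0)
        expected = -a * h * (c0 / rho_ij) * (-1e-4) / (5e-3 ** 2 + b * h ** 2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 0  # approaching pair resists compression


def brute_fluid_forces(sys_, box, cfg):
    """Exhaustive double-loop reference for the fluid momentum equation."""
    from perisim.sph import kernel_gradient, tait_pressure, viscous_term
    n = sys_.n
    L = box.axial_length
    press = tait_pressure(sys_.densities, cfg.c0, cfg.rho0,
                          cfg.tait_prefactor_mode)
    f = np.zeros((n, 3))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = sys_.positions[i] - sys_.positions[j]
            d[0] -= L * round(d[0] / L)
            r = np.linalg.norm(d)
            if r >= SUPPORT_FACTOR * cfg.h:
                continue
            e = d / r
            pi_ij = viscous_term(sys_.velocities[i] - sys_.velocities[j], d,
                                 sys_.densities[i] + sys_.densities[j],
                                 cfg.a, cfg.b, cfg.h, cfg.c0)
            grad = kernel_gradient(r, e, cfg.h)
            f[i] -= sys_.masses[i] * sys_.masses[j] * (
                press[i] / sys_.densities[i] ** 2
                + press[j] / sys_.densities[j] ** 2 + pi_ij) * grad
    return f


class TestFluidPairForces:
    def make_blob(self, rng, n=20):
        cfg = SimulationConfig(c0=5.0)
        box = BoxGeometry(0.1)
        pos = rng.uniform([0, -4e-3, -4e-3], [0.1, 4e-3, 4e-3], (n, 3))
        sys_ = make_system(pos, velocities=0.01 * rng.normal(size=(n, 3)),
                           masses=np.full(n, 1e-4))
        compute_density(sys_, box, cfg.h)
        return sys_, box, cfg

    def test_equal_pressure_pair_repels_symmetrically(self):
        cfg = SimulationConfig(c0=5.0)
        box = BoxGeometry(0.1)
        sys_ = make_system([[0.05, 0, 0], [0.055, 0, 0]],
                           masses=np.full(2, 1e-4))
        sys_.densities = np.full(2, 1.02 * cfg.rho0)  # compressed: P > 0
        f = fluid_pair_forces(sys_, box, cfg)
        np.testing.assert_allclose(f[0], -f[1], rtol=1e-14)
        assert f[0][0] < 0 < f[1][0]  # pointing apart

    def test_matches_brute_force_reference(self, rng):
        sys_, box, cfg = self.make_blob(rng)
        f = fluid_pair_forces(sys_, box, cfg)
        np.testing.assert_allclose(f, brute_fluid_forces(sys_, box, cfg),
                                   rtol=1e-10, atol=1e-18)

    def test_momentum_conserved_to_machine_precision(self, rng):
        sys_, box, cfg = self.make_blob(rng, n=40)
        f = fluid_pair_forces(sys_, box, cfg)
        assert np.linalg.norm(f.sum(axis=0)) / np.abs(f).sum() < 1e-12

    def test_viscosity_dissipates_relative_motion(self):
        """Isolated approaching pair with no pressure force: kinetic
        energy in the relative coordinate decreases over a step."""
        cfg = SimulationConfig(c0=5.0, a=0.5)
        box = BoxGeometry(0.1)
        sys_ = make_system([[0.05, 0, 0], [0.056, 0, 0]],
                           velocities=np.array([[0.05, 0, 0], [-0.05, 0, 0]]),
                           masses=np.full(2, 1e-4))
        sys_.densities = np.full(2, cfg.rho0)  # P = 0 exactly
        from perisim.core import integrate_step
        sys_.forces = fluid_pair_forces(sys_, box, cfg)
        v_rel0 = sys_.velocities[0] - sys_.velocities[1]
        integrate_step(sys_, box, lambda s: fluid_pair_forces(s, box, cfg), cfg.dt)
        v_rel1 = sys_.velocities[0] - sys_.velocities[1]
        assert np.linalg.norm(v_rel1) < np.linalg.norm(v_rel0)

    def test_overlapping_particles_error(self):
        cfg = SimulationConfig()
        box = BoxGeometry(0.1)
        sys_ = make_system([[0.05, 0, 0], [0.05, 0, 0]], masses=np.full(2, 1e-4))
        with pytest.raises(ValueError, match="overlapping"):
            fluid_pair_forces(sys_, box, cfg)
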