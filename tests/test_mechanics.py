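"""Force/energy consistency and elementary mechanics behaviour."""

import numpy as np
import pytest

from samsce import mechanics
from samsce.config import MechanicsParams, MorseParams
from samsce.errors import (DegenerateGeometryError, NumericalBlowupError,
                           SingularConfigurationError)
from samsce.mechanics import (Engine, adhesion_force, assemble_forces,
                              cell_stresses, euler_step,
                              in_plane_tensile_stress, morse_energy,
                              morse_equilibrium_distance, morse_force,
                              total_energy, wall_spring_energy,
                              wall_spring_force)
from samsce.simulation import _circle_ring, _sunflower
from samsce.tissue import Cell, Tissue, flatten

from conftest import circle_ring

MECH = MechanicsParams()


def numeric_gradient(f, x, h=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        xp = x.copy().ravel()
        xm = x.copy().ravel()
        xp[i] += h
        xm[i] -= h
        g.ravel()[i] = (f(xp.reshape(x.shape)) - f(xm.reshape(x.shape))) / (2 * h)
    return g


class TestWallSpring:
    def test_equilibrium_triplet_has_zero_force(self):
        ell = 0.5
        trip = [(0, 0), (ell, 0), (2 * ell, 0)]
        f = wall_spring_force(trip, 3.0, ell, 1.0, np.pi)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_stretched_collinear_chain(self):
        """At double the rest spacing, end nodes are pulled in with k*ell."""
        ell, k = 0.5, 3.0
        trip = [(0, 0), (2 * ell, 0), (4 * ell, 0)]
        f = wall_spring_force(trip, k, ell, 1.0, np.pi)
        assert f[0] == pytest.approx([k * ell, 0.0])
        assert f[2] == pytest.approx([-k * ell, 0.0])
        assert np.allclose(f[1], 0.0, atol=1e-12)

    def test_forces_sum_to_zero_and_match_fd(self, rng):
        for _ in range(10):
            trip = rng.normal(size=(3, 2))
            if min(np.linalg.norm(trip[1] - trip[0]),
                   np.linalg.norm(trip[2] - trip[1])) < 0.1:
                continue
            f = wall_spring_force(trip, 2.0, 0.4, 1.5, 2.7)
            assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)
            g = numeric_gradient(
                lambda x: wall_spring_energy(x, 2.0, 0.4, 1.5, 2.7), trip)
            assert np.allclose(f, -g, rtol=1e-4, atol=1e-7)

    def test_right_angle_bend_restores_toward_flat(self):
        trip = np.array([(1.0, 0.0), (0.0, 0.0), (0.0, 1.0)])
        f = wall_spring_force(trip, 0.0, 1.0, 2.0, np.pi)
        g = numeric_gradient(lambda x: wall_spring_energy(x, 0.0, 1.0, 2.0, np.pi),
                             trip)
        assert np.allclose(f, -g, rtol=1e-4, atol=1e-8)
        # the end nodes are pushed apart (opening the angle toward pi)
        assert f[0][1] < 0 and f[2][0] < 0

    def test_coincident_nodes_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            wall_spring_force([(0, 0), (0, 0), (1, 0)], 1.0, 0.4, 1.0, np.pi)


class TestMorse:
    P = MorseParams(U=0.4, W=0.05, xi=0.8, gamma=2.5)

    def test_zero_force_at_equilibrium_distance(self):
        r_star = morse_equilibrium_distance(self.P)
        f = morse_force([0.0, 0.0], [r_star, 0.0], self.P)
        assert np.allclose(f, 0.0, atol=1e-10)

    def test_decays_to_zero_beyond_attractive_peak(self):
        rs = np.linspace(2 * morse_equilibrium_distance(self.P), 40, 50)
        mags = [np.linalg.norm(morse_force([0, 0], [r, 0], self.P)) for r in rs]
        assert all(a >= b - 1e-15 for a, b in zip(mags, mags[1:]))
        assert mags[-1] < 1e-6

    def test_newtons_third_law(self, rng):
        p, q = rng.normal(size=2), rng.normal(size=2) + 3.0
        assert np.allclose(morse_force(p, q, self.P), -morse_force(q, p, self.P))

    def test_matches_fd_gradient(self, rng):
        for _ in range(10):
            p = rng.normal(size=2)
            q = p + rng.uniform(0.3, 4.0) * _unit(rng)
            f = morse_force(p, q, self.P)
            g = numeric_gradient(lambda x: morse_energy(x, q, self.P), p)
            assert np.allclose(f, -g, rtol=1e-4, atol=1e-9)

    def test_zero_separation_is_singular(self):
        with pytest.raises(SingularConfigurationError):
            morse_force([1.0, 1.0], [1.0, 1.0], self.P)


def _unit(rng):
    a = rng.uniform(0, 2 * np.pi)
    return np.array([np.cos(a), np.sin(a)])


class TestAdhesion:
    def test_rest_length_gives_zero(self):
        assert np.allclose(adhesion_force([0, 0], [0.3, 0], 2.0, 0.3), 0.0)

    def test_hooke_at_double_and_zero_separation(self):
        f = adhesion_force([0, 0], [0.6, 0], 2.0, 0.3)
        assert f == pytest.approx([2.0 * 0.3, 0.0])  # attractive
        f0 = adhesion_force([0, 0], [0.0, 0.0], 2.0, 0.3)
        assert np.linalg.norm(f0) == pytest.approx(2.0 * 0.3)  # repulsive

    def test_missing_partner_is_noop(self):
        assert np.allclose(adhesion_force([1, 2], None, 2.0, 0.3), 0.0)


def _one_cell_tissue(m_internal=8, eta=None):
    t = Tissue()
    ring = _circle_ring((0.0, 0.0), 2.5, 32)
    internal = _sunflower((0.0, 0.0), 1.2, m_internal,
                          np.random.default_rng(3))
    c = Cell(0, ring, internal, 3, eta or MECH.eta_default)
    c.k_bend[:] = MECH.k_bend_low
    t.add_cell(c)
    return t, c


class TestAssembly:
    def test_internal_forces_sum_to_zero(self):
        t, _ = _one_cell_tissue()
        flat, forces = assemble_forces(t, MECH)
        fmax = np.abs(forces).max()
        assert np.abs(forces.sum(axis=0)).max() <= 1e-8 * max(fmax, 1.0)

    def test_far_separated_cells_do_not_interact(self):
        t = Tissue()
        for cid, cx in ((0, 0.0), (1, 100.0)):
            ring = _circle_ring((cx, 0.0), 2.5, 32)
            c = Cell(cid, ring, np.array([[cx, 0.0]]), 3, MECH.eta_default)
            c.k_bend[:] = MECH.k_bend_low
            t.add_cell(c)
        flat, forces = assemble_forces(t, MECH)
        t0 = Tissue()
        ring = _circle_ring((0.0, 0.0), 2.5, 32)
        c = Cell(0, ring, np.array([[0.0, 0.0]]), 3, MECH.eta_default)
        c.k_bend[:] = MECH.k_bend_low
        t0.add_cell(c)
        _, f_alone = assemble_forces(t0, MECH)
        assert np.allclose(forces[:32], f_alone[:32], atol=1e-12)

    def test_total_force_matches_fd_of_total_energy(self):
        """Assembled forces are the negative gradient of the summed potentials."""
        t, _ = _one_cell_tissue(m_internal=5)
        flat = flatten(t)
        forces = mechanics.compute_forces_flat(flat, MECH, wwd=np.empty((0, 2),
                                                                        dtype=np.int64))

        def energy_at(pos_flat):
            f2 = flatten(t)
            f2.pos = pos_flat.reshape(flat.pos.shape).copy()
            return total_energy(f2, MECH, wwd=np.empty((0, 2), dtype=np.int64))

        g = numeric_gradient(energy_at, flat.pos.ravel(), h=1e-6)
        g = g.reshape(flat.pos.shape)
        scale = max(np.abs(forces).max(), 1e-9)
        assert np.allclose(forces, -g, atol=2e-4 * scale, rtol=1e-4)

    def test_mirror_symmetric_pair_gets_mirror_forces(self):
        t = Tissue()
        for cid, cx in ((0, -2.6), (1, 2.6)):
            ring = _circle_ring((cx, 0.0), 2.5, 32)
            c = Cell(cid, ring, np.array([[cx, 0.0]]), 3, MECH.eta_default)
            c.k_bend[:] = MECH.k_bend_low
            t.add_cell(c)
        flat, forces = assemble_forces(t, MECH)
        sl0, sl1 = flat.wall_slices[0], flat.wall_slices[1]
        net0 = forces[sl0].sum(axis=0)
        net1 = forces[sl1].sum(axis=0)
        # x -> -x symmetry: net x-forces opposite, net y-forces equal
        assert net0[0] == pytest.approx(-net1[0], abs=1e-9)
        assert net0[1] == pytest.approx(net1[1], abs=1e-9)
        assert np.allclose(np.sort(np.hypot(*forces[sl0].T)),
                           np.sort(np.hypot(*forces[sl1].T)), atol=1e-9)


class TestEuler:
    def test_zero_force_leaves_positions(self):
        t, c = _one_cell_tissue()
        flat = flatten(t)
        before = flat.pos.copy()
        flat.pos += (MECH.dt / flat.eta)[:, None] * 0.0
        assert np.array_equal(flat.pos, before)

    def test_damping_scales_displacement(self):
        t1, c1 = _one_cell_tissue(eta=MECH.eta_default)
        t2, c2 = _one_cell_tissue(eta=2 * MECH.eta_default)
        f1 = euler_step(t1, MECH)
        f2 = euler_step(t2, MECH)
        ring0 = _circle_ring((0.0, 0.0), 2.5, 32)
        d1 = np.abs(c1.wall - ring0).max()
        d2 = np.abs(c2.wall - ring0).max()
        assert d1 == pytest.approx(2 * d2, rel=1e-9)

    def test_relaxation_energy_never_increases(self):
        t, _ = _one_cell_tissue()
        eng = Engine(t, MECH)
        energies = []
        for _ in range(20):
            energies.append(total_energy(eng.flat, MECH))
            eng.advance(20.0, scatter=False)
        assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))

    def test_blowup_raises_named_error(self):
        t, c = _one_cell_tissue()
        c.wall[0] = [np.inf, np.inf]
        with pytest.raises(NumericalBlowupError):
            euler_step(t, MECH)


class TestTensileStress:
    def test_rest_spacing_gives_zero(self):
        ell = MECH.ell
        n = 12
        # regular polygon with side exactly ell
        r = ell / (2 * np.sin(np.pi / n))
        c = Cell(0, circle_ring(r, n), np.array([[0.0, 0.0]]), 3, 1.0)
        assert in_plane_tensile_stress(c, 3, MECH) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_double_spacing_equals_k_ell(self):
        """The printed closed form: S = k_lin * ell for 2*ell spacings."""
        ell, k = MECH.ell, MECH.k_lin
        ring = np.array([[x, 0.0] for x in np.arange(8) * 2 * ell]
                        + [[x, 5.0] for x in np.arange(8)[::-1] * 2 * ell])
        c = Cell(0, ring, np.array([[4 * ell, 2.5]]), 3, 1.0)
        assert in_plane_tensile_stress(c, 3, MECH) == pytest.approx(k * ell)

    def test_uniformly_inflated_ring_is_homogeneous(self):
        n = 16
        alpha = 1.5
        r = alpha * MECH.ell / (2 * np.sin(np.pi / n))
        c = Cell(0, circle_ring(r, n), np.array([[0.0, 0.0]]), 3, 1.0)
        s = cell_stresses(c, MECH)
        assert np.allclose(s, s[0], rtol=1e-9)
        assert s[0] > 0

    def test_vectorised_matches_single_node(self, rng):
        ring = circle_ring(2.0, 14) + rng.normal(scale=0.1, size=(14, 2))
        c = Cell(0, ring, np.array([[0.0, 0.0]]), 3, 1.0)
        s = cell_stresses(c, MECH)
        for j in range(14):
            assert s[j] == pytest.approx(in_plane_tensile_stress(c, j, MECH))

    def test_degenerate_tangent_rejected(self):
        ring = circle_ring(2.0, 12)
        ring[2] = ring[0]  # prev == next around node 1
        c = Cell(0, ring, np.array([[0.0, 0.0]]), 3, 1.0)
        with pytest.raises(DegenerateGeometryError):
            in_plane_tensile_stress(c, 1, MECH)


class TestSingleCellShapes:
    def test_isotropic_cell_stays_circular(self):
        from samsce import geometry
        from samsce.growth import partition_side_end

        t, c = _one_cell_tissue(m_internal=8)
        partition_side_end(c, None, 45.0, MECH)
        eng = Engine(t, MECH)
        eng.advance(1200.0)
        ratio, _ = geometry.aspect_ratio_and_orientation(c.wall)
        assert ratio < 1.05

    def test_polarized_cell_elongates_along_axis(self):
        from samsce import geometry
        from samsce.growth import partition_side_end

        t = Tissue()
        ring = _circle_ring((0.0, 0.0), 2.546, 40)
        internal = _sunflower((0.0, 0.0), 1.4, 8, np.random.default_rng(3))
        c = Cell(0, ring, internal, 3, MECH.eta_default)
        t.add_cell(c)
        partition_side_end(c, np.array([0.0, 1.0]), 45.0, MECH)
        eng = Engine(t, MECH)
        eng.advance(2400.0)
        ratio, angle = geometry.aspect_ratio_and_orientation(c.wall)
        assert ratio > 1.1
        assert angle > 45.0  # elongated apical-basally, along v
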