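"""Contraction FEM: rotations, element integrals, assembly, solve, strain."""

import numpy as np
import pytest

from cardiosync import fixtures, hexfem, mechanics
from cardiosync.hexfem import ElementQuadrature
from cardiosync.mechanics import (MaterialParams, TwitchParams, active_stress,
                                  assemble_global, bond_stress_matrix,
                                  element_active_force, element_stiffness,
                                  fiber_rotation_matrix, midwall_ring_samples,
                                  rotate_elasticity, solve_frame,
                                  strain_at_samples, unit_active_force)

UNIT_CUBE = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def isotropic_elasticity(E=10.0, nu=0.3):
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def distorted_hex(seed=0, scale=0.2):
    rng = np.random.default_rng(seed)
    return UNIT_CUBE + scale * rng.uniform(-0.5, 0.5, size=(8, 3))


class TestFiberRotation:
    def test_fiber_along_x_gives_identity(self):
        M = fiber_rotation_matrix(np.array([1.0, 0.0, 0.0]),
                                  frame=np.eye(3))
        assert np.allclose(M, np.eye(6), atol=1e-14)

    def test_identity_material_invariant_and_orthogonal(self):
        M = fiber_rotation_matrix(np.array([0.3, -0.5, 0.81]))
        assert np.allclose(M @ np.eye(6) @ M.T, np.eye(6), atol=1e-12)
        assert np.allclose(M @ M.T, np.eye(6), atol=1e-12)

    def test_composition_of_rotations(self):
        Q1 = rotation_matrix([0, 0, 1], 0.7)
        Q2 = rotation_matrix([1, 1, 0], -0.4)
        M12 = bond_stress_matrix(Q1 @ Q2)
        assert np.allclose(M12, bond_stress_matrix(Q1) @ bond_stress_matrix(Q2),
                           atol=1e-12)
        R12 = fiber_rotation_matrix(Q1 @ Q2 @ np.array([1.0, 0, 0]),
                                    frame=Q1 @ Q2)
        R1 = fiber_rotation_matrix(Q1 @ np.array([1.0, 0, 0]), frame=Q1)
        R2 = fiber_rotation_matrix(Q2 @ np.array([1.0, 0, 0]), frame=Q2)
        assert np.allclose(R12, R1 @ R2, atol=1e-12)

    def test_transformed_elasticity_stays_spd(self):
        C = MaterialParams().elasticity_matrix()
        rng = np.random.default_rng(1)
        for _ in range(5):
            f = rng.normal(size=3)
            Cg = rotate_elasticity(C, f / np.linalg.norm(f))
            assert np.allclose(Cg, Cg.T, atol=1e-10)
            assert np.linalg.eigvalsh(Cg).min() > 0

    def test_degenerate_frame_rejected(self):
        with pytest.raises(ValueError):
            fiber_rotation_matrix(np.zeros(3))
        with pytest.raises(ValueError):
            fiber_rotation_matrix(np.array([1.0, 0, 0]),
                                  frame=np.ones((3, 3)))


class TestElementStiffness:
    def test_unit_cube_matches_dense_high_order_oracle(self):
        """2x2x2-point result vs an independent 4x4x4 Gauss integration."""
        C = isotropic_elasticity()
        K = element_stiffness(UNIT_CUBE, C)

        x, w = np.polynomial.legendre.leggauss(4)
        signs = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                          [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)
        K_ref = np.zeros((24, 24))
        for ia, a in enumerate(x):
            for ib, b in enumerate(x):
                for ic, c in enumerate(x):
                    one = 1.0 + np.array([a, b, c]) * signs
                    dN = np.empty((8, 3))
                    dN[:, 0] = 0.125 * signs[:, 0] * one[:, 1] * one[:, 2]
                    dN[:, 1] = 0.125 * signs[:, 1] * one[:, 0] * one[:, 2]
                    dN[:, 2] = 0.125 * signs[:, 2] * one[:, 0] * one[:, 1]
                    J = UNIT_CUBE.T @ dN
                    dNdx = dN @ np.linalg.inv(J)
                    B = np.zeros((6, 24))
                    for n in range(8):
                        dx, dy, dz = dNdx[n]
                        B[0, 3 * n] = dx
                        B[1, 3 * n + 1] = dy
                        B[2, 3 * n + 2] = dz
                        B[3, 3 * n + 1] = dz
                        B[3, 3 * n + 2] = dy
                        B[4, 3 * n] = dz
                        B[4, 3 * n + 2] = dx
                        B[5, 3 * n] = dy
                        B[5, 3 * n + 1] = dx
                    K_ref += B.T @ C @ B * np.linalg.det(J) * w[ia] * w[ib] * w[ic]
        assert np.abs(K - K_ref).max() < 1e-10

    def test_symmetry_and_rigid_modes(self):
        C = MaterialParams().elasticity_matrix()
        K = element_stiffness(distorted_hex(2), rotate_elasticity(C, [0.6, 0.8, 0.0]))
        assert np.abs(K - K.T).max() < 1e-12 * np.abs(K).max()
        # six near-zero eigenvalues: rigid translations and rotations
        ev = np.abs(np.linalg.eigvalsh(K))
        assert (ev < 1e-9 * ev.max()).sum() == 6
        for ax in range(3):
            u = np.zeros(24)
            u[ax::3] = 1.0
            assert np.abs(K @ u).max() < 1e-10 * np.abs(K).max()

    def test_inverted_element_rejected(self):
        bad = UNIT_CUBE.copy()
        bad[[0, 1]] = bad[[1, 0]]
        with pytest.raises(Exception):
            element_stiffness(bad, isotropic_elasticity())


class TestActiveForce:
    def test_zero_stress_zero_force(self):
        f = element_active_force(UNIT_CUBE, 0.0, np.array([1.0, 0, 0]))
        assert np.all(f == 0)

    def test_unit_cube_closed_form(self):
        """Unit fiber stress along x: +-1/4 on the two x-faces' nodes."""
        f = element_active_force(UNIT_CUBE, 1.0, np.array([1.0, 0, 0]))
        expected = np.zeros(24)
        for n, sx in enumerate(UNIT_CUBE[:, 0]):
            expected[3 * n] = 0.25 if sx == 0 else -0.25
        assert np.abs(f - expected).max() < 1e-10

    def test_self_equilibrated(self):
        coords = distorted_hex(5)
        f = element_active_force(coords, 2.3, np.array([0.6, 0.0, 0.8]))
        F = f.reshape(8, 3)
        assert np.abs(F.sum(axis=0)).max() < 1e-10
        moments = np.cross(coords, F).sum(axis=0)
        assert np.abs(moments).max() < 1e-9


class TestAssembly:
    def test_disconnected_elements_block_diagonal(self):
        mesh = fixtures.make_slab_mesh(1, 1, 1)
        far = fixtures.make_slab_mesh(1, 1, 1)
        import copy
        m = copy.deepcopy(mesh)
        m.nodes = np.vstack([mesh.nodes, far.nodes + 10.0])
        m.elements = np.vstack([mesh.elements, far.elements + 8])
        m.fibers = np.vstack([mesh.fibers, far.fibers])
        m.part = np.concatenate([m.part, far.part])
        m.layer = np.concatenate([m.layer, far.layer])
        m.grid_index = np.vstack([m.grid_index, far.grid_index])
        m.surfaces = {}
        model = assemble_global(m, MaterialParams(), constraint_surface="none")
        K = model.K.toarray()
        assert np.abs(K[:24, 24:]).max() == 0.0
        assert np.abs(K - K.T).max() < 1e-12 * np.abs(K).max()

    def test_constrained_system_positive_definite(self):
        slab = fixtures.make_slab_mesh(2, 2, 2)
        model = assemble_global(slab, MaterialParams(), base_spring=50.0,
                                constraint_surface="zmax")
        ev = np.linalg.eigvalsh(model.K.toarray())
        assert ev.min() > 0

    def test_sparse_equals_dense_bruteforce(self):
        """Assembled sparse operator vs per-element dense scatter (<=20 elems)."""
        slab = fixtures.make_slab_mesh(3, 2, 1, h=1.3, fiber=(0.6, 0.0, 0.8))
        model = assemble_global(slab, MaterialParams(), constraint_surface="none")
        C = rotate_elasticity(MaterialParams().elasticity_matrix(),
                              slab.fibers[0])
        n_dof = 3 * len(slab.nodes)
        K_ref = np.zeros((n_dof, n_dof))
        for conn in slab.elements:
            Ke = element_stiffness(slab.nodes[conn], C)
            dof = (3 * conn[:, None] + np.arange(3)).ravel()
            K_ref[np.ix_(dof, dof)] += Ke
        assert np.abs(model.K.toarray() - K_ref).max() < 1e-10 * np.abs(K_ref).max()


class TestActiveStress:
    TW = TwitchParams(T_max=12.0, t_rise=60.0, t_decay=80.0, duration=380.0)

    def test_zero_before_activation_and_after_duration(self):
        assert active_stress(99.0, 100.0, self.TW) == 0.0
        assert active_stress(100.0, 100.0, self.TW) == 0.0
        assert active_stress(100.0 + 380.0, 100.0, self.TW) == 0.0

    def test_peak_equals_tmax(self):
        t = np.linspace(0, 380, 38001)
        trace = active_stress(t, 0.0, self.TW)
        assert abs(trace.max() - self.TW.T_max) < 1e-9
        assert np.all(trace >= 0)

    def test_shift_invariance(self):
        t = np.linspace(0, 500, 2001)
        a = active_stress(t, 40.0, self.TW)
        b = active_stress(t + 25.0, 65.0, self.TW)
        assert np.allclose(a, b, atol=1e-12)

    def test_continuity_at_rise_end(self):
        eps = 1e-9
        lo = active_stress(self.TW.t_rise - eps, 0.0, self.TW)
        hi = active_stress(self.TW.t_rise + eps, 0.0, self.TW)
        assert abs(lo - hi) < 1e-6


@pytest.fixture(scope="module")
def slab_model():
    slab = fixtures.make_slab_mesh(4, 2, 2, h=2.0)
    model = assemble_global(slab, MaterialParams(), base_spring=100.0,
                            constraint_surface="xmin")
    return slab, model


class TestSolveFrame:

    def test_zero_before_earliest_activation(self, slab_model):
        slab, model = slab_model
        act = np.full(len(slab.nodes), 50.0)
        d = solve_frame(model, slab, act, TwitchParams(), 10.0)
        assert np.all(d.u == 0)

    def test_residual_small(self, slab_model):
        slab, model = slab_model
        act = fixtures.make_activation_fixture(slab, "linear",
                                               gradient_ms_per_mm=2.0)
        d = solve_frame(model, slab, act, TwitchParams(), 80.0)
        t_act_e = act[slab.elements].mean(axis=1)
        sig = active_stress(np.full(len(slab.elements), 80.0), t_act_e,
                            TwitchParams())
        F = np.zeros(model.K.shape[0])
        np.add.at(F, model.dof_index.ravel(), (sig[:, None] * model.G).ravel())
        r = model.K @ d.u.ravel() - F
        assert np.linalg.norm(r) < 1e-8 * np.linalg.norm(F)
        # energy consistency at the solution
        assert d.u.ravel() @ model.K @ d.u.ravel() == pytest.approx(
            d.u.ravel() @ F, rel=1e-8)

    def test_deterministic(self, slab_model):
        slab, model = slab_model
        act = fixtures.make_activation_fixture(slab, "two-zone")
        d1 = solve_frame(model, slab, act, TwitchParams(), 120.0)
        d2 = solve_frame(model, slab, act, TwitchParams(), 120.0)
        assert np.array_equal(d1.u, d2.u)


class TestStrain:
    def make_samples(self, mesh, xi, chat=(1.0, 0.0, 0.0)):
        return mechanics.SamplePoints(
            points=np.zeros((1, 3)), element=np.array([0]),
            xi=np.array([xi]), chat=np.array([chat]),
            angles=np.zeros(1), layer=np.ones(1, dtype=int))

    def test_patch_test_linear_field(self):
        """Prescribed linear displacement reproduces its constant strain."""
        mesh = fixtures.make_slab_mesh(1, 1, 1)
        mesh.nodes = distorted_hex(9, scale=0.3)
        A = np.array([[0.02, 0.01, 0.0], [0.0, -0.015, 0.005],
                      [0.01, 0.0, 0.03]])
        u = mesh.nodes @ A.T
        E_exact = 0.5 * (A + A.T + A.T @ A)
        rng = np.random.default_rng(4)
        for xi in rng.uniform(-0.9, 0.9, size=(5, 3)):
            s = self.make_samples(mesh, xi)
            out = strain_at_samples(mesh, mechanics.DisplacementField(u=u), s)
            assert np.abs(out.E[0] - E_exact).max() < 1e-10

    def test_zero_displacement_zero_strain(self):
        mesh = fixtures.make_slab_mesh(1, 1, 1)
        s = self.make_samples(mesh, (0.0, 0.0, 0.0))
        out = strain_at_samples(mesh, mechanics.DisplacementField(
            u=np.zeros((8, 3))), s)
        assert np.all(out.E == 0) and out.ecc[0] == 0 and out.e1[0] == 0

    def test_uniform_stretch_closed_form(self):
        mesh = fixtures.make_slab_mesh(1, 1, 1)
        u = np.zeros((8, 3))
        u[:, 0] = 0.1 * mesh.nodes[:, 0]  # stretch 1.1 along x
        s = self.make_samples(mesh, (0.2, -0.3, 0.1))
        out = strain_at_samples(mesh, mechanics.DisplacementField(u=u), s)
        assert out.ecc[0] == pytest.approx((1.1 ** 2 - 1) / 2, abs=1e-12)
        assert out.e1[0] == pytest.approx(0.105, abs=1e-12)

    def test_rigid_rotation_objectivity(self):
        mesh = fixtures.make_slab_mesh(1, 1, 1)
        mesh.nodes = distorted_hex(11, scale=0.25)
        Q = rotation_matrix([0.3, 1.0, -0.2], 0.8)
        u = mesh.nodes @ Q.T - mesh.nodes
        s = self.make_samples(mesh, (0.0, 0.2, -0.4))
        out = strain_at_samples(mesh, mechanics.DisplacementField(u=u), s)
        assert np.abs(out.E[0]).max() < 1e-10


class TestRingSamples:
    def test_thirty_ordered_equiangular_samples(self, coarse_mesh):
        s = midwall_ring_samples(coarse_mesh, 7, 30)
        assert len(s.angles) == 30
        gaps = np.diff(np.concatenate([s.angles, [s.angles[0] + 2 * np.pi]]))
        assert np.abs(gaps - 2 * np.pi / 30).max() < 1e-9

    def test_samples_live_in_requested_layer(self, coarse_mesh):
        for layer in (6, 9):
            s = midwall_ring_samples(coarse_mesh, layer, 12)
            assert np.all(coarse_mesh.layer[s.element] == layer)
            assert np.all(coarse_mesh.part[s.element] == "lv")

    def test_circumferential_vectors_perpendicular_to_radius(self, coarse_mesh):
        s = midwall_ring_samples(coarse_mesh, 7, 30)
        r = s.points.copy()
        r[:, 2] = 0.0
        dots = np.einsum("ij,ij->i", s.chat, r)
        assert np.abs(dots).max() < 1e-9
        assert np.abs(np.linalg.norm(s.chat, axis=1) - 1).max() < 1e-12

    def test_invalid_layer_rejected(self, coarse_mesh):
        with pytest.raises(ValueError):
            midwall_ring_samples(coarse_mesh, 0, 30)
        with pytest.raises(ValueError):
            midwall_ring_samples(coarse_mesh, 7, 3)


def test_synchrony_limit_uniform_ring(axisymmetric_mesh):
    """Simultaneous activation on an axisymmetric LV: uniform ring strain."""
    model = assemble_global(axisymmetric_mesh, MaterialParams())
    d = solve_frame(model, axisymmetric_mesh,
                    np.zeros(axisymmetric_mesh.n_nodes), TwitchParams(), 60.0)
    s = midwall_ring_samples(axisymmetric_mesh, 7, 30)
    out = strain_at_samples(axisymmetric_mesh, d, s)
    cov = out.ecc.std() / abs(out.ecc.mean())
    assert cov < 0.02
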