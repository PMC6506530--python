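import numpy as np
import pytest

from talonmorph.fea import (BONE, ElasticMaterial, LoadCase, apply_load_case,
                            assemble_stiffness, grip_load_case,
                            scale_to_reference_area, solve, solve_grip,
                            von_mises)
from talonmorph.geometry import TetMesh, structured_box_mesh


SINGLE_TET = TetMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.]]),
                     np.array([[0, 1, 2, 3]]))


def uniaxial_bar(n=2, length=5.0):
    """Structured bar along z with consistent end traction and minimal,
    exact-solution-compatible lateral pins."""
    m = structured_box_mesh(n, n, 5 * n, 1.0, 1.0, length)
    n00 = int(np.where(np.all(np.isclose(m.nodes, [0, 0, 0]), axis=1))[0][0])
    n10 = int(np.where(np.all(np.isclose(m.nodes, [1, 0, 0]), axis=1))[0][0])
    m.node_sets["pin_xy"] = np.array([n00])
    m.node_sets["pin_y"] = np.array([n10])
    return m


def end_traction(mesh, total_force):
    """Consistent nodal forces for uniform traction on the z = max face."""
    f = np.zeros(3 * mesh.n_nodes)
    bf = mesh.boundary_faces()
    zmax = mesh.nodes[:, 2].max()
    on_end = np.all(np.abs(mesh.nodes[bf][:, :, 2] - zmax) < 1e-12, axis=1)
    area = 0.0
    for tri in bf[on_end]:
        a, b, c = mesh.nodes[tri]
        ar = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
        area += ar
        for v in tri:
            f[3 * v + 2] += total_force * ar / 3.0
    return f / area


class TestVonMises:
    def test_invariants(self):
        assert von_mises(np.array([5.0, 0, 0, 0, 0, 0])) == pytest.approx(5.0, abs=1e-9)
        assert von_mises(np.array([0, 0, 0, 2.0, 0, 0])) == pytest.approx(
            2.0 * np.sqrt(3), abs=1e-9)
        assert von_mises(np.array([3.0, 3.0, 3.0, 0, 0, 0])) == pytest.approx(0.0, abs=1e-9)

    def test_matches_principal_stress_form(self, rng):
        s = rng.normal(size=6)
        T = np.array([[s[0], s[3], s[5]], [s[3], s[1], s[4]], [s[5], s[4], s[2]]])
        p = np.linalg.eigvalsh(T)
        expected = np.sqrt(((p[0] - p[1]) ** 2 + (p[1] - p[2]) ** 2 +
                            (p[2] - p[0]) ** 2) / 2)
        assert von_mises(s) == pytest.approx(expected, abs=1e-9)


class TestAssembly:
    def test_single_tet_rank_deficiency_is_six(self):
        K = assemble_stiffness(SINGLE_TET, BONE).toarray()
        assert np.abs(K - K.T).max() == 0.0
        rank = np.linalg.matrix_rank(K, tol=1e-8 * np.abs(K).max())
        assert rank == 6  # 12 DOFs minus 6 rigid-body modes

    def test_translation_nullspace(self, coarse_talon):
        _, tet, _ = coarse_talon
        K = assemble_stiffness(tet, BONE)
        for ax in range(3):
            v = np.zeros(3 * tet.n_nodes)
            v[ax::3] = 1.0
            assert np.abs(K @ v).max() < 1e-8 * np.abs(K.data).max()

    def test_against_dense_hand_assembly(self, rng):
        # two-tet bar; oracle assembled element by element with explicit
        # shape-function gradients and loops, no shared code path
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [1, 1, 1.]])
        tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
        mesh = TetMesh(nodes, tets)
        mesh.fix_orientation()
        K = assemble_stiffness(mesh, BONE).toarray()

        D = BONE.d_matrix()
        K_ref = np.zeros((15, 15))
        for tet in mesh.tets:
            p = nodes[tet]
            M = np.hstack([np.ones((4, 1)), p])
            C = np.linalg.inv(M)          # rows: [a_i; b_i; c_i; d_i]
            vol = abs(np.linalg.det(M)) / 6.0
            B = np.zeros((6, 12))
            for i in range(4):
                bx, by, bz = C[1, i], C[2, i], C[3, i]
                B[:, 3 * i:3 * i + 3] = [[bx, 0, 0], [0, by, 0], [0, 0, bz],
                                         [by, bx, 0], [0, bz, by], [bz, 0, bx]]
            ke = vol * B.T @ D @ B
            dof = np.concatenate([[3 * v, 3 * v + 1, 3 * v + 2] for v in tet])
            for a in range(12):
                for b in range(12):
                    K_ref[dof[a], dof[b]] += ke[a, b]
        np.testing.assert_allclose(K, K_ref, atol=1e-10 * np.abs(K_ref).max())

    def test_inverted_element_reported(self):
        bad = TetMesh(SINGLE_TET.nodes.copy(), np.array([[0, 2, 1, 3]]))
        with pytest.raises(ValueError, match="element 0"):
            assemble_stiffness(bad, BONE)


class TestScaling:
    def test_equal_area_identity(self, coarse_talon):
        _, tet, _ = coarse_talon
        scaled, spec = scale_to_reference_area(tet, tet.surface_area())
        assert spec.k == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(scaled.nodes, tet.nodes, rtol=1e-12)

    def test_quadruple_area_halves_edges(self, coarse_talon):
        _, tet, _ = coarse_talon
        area = tet.surface_area()
        scaled, spec = scale_to_reference_area(tet, area / 4.0)
        assert spec.k == pytest.approx(0.5, rel=1e-9)
        assert scaled.surface_area() == pytest.approx(area / 4, rel=1e-6)

    def test_recomputed_area_matches_reference(self, coarse_talon):
        _, tet, _ = coarse_talon
        scaled, _ = scale_to_reference_area(tet, 123.4)
        assert scaled.surface_area() == pytest.approx(123.4, rel=1e-6)

    def test_literal_printed_formula_is_dimensionally_wrong(self, coarse_talon):
        _, tet, _ = coarse_talon
        scaled, spec = scale_to_reference_area(tet, tet.surface_area(),
                                               literal_formula=True)
        # the literal reading does NOT reproduce the reference area
        assert scaled.surface_area() != pytest.approx(tet.surface_area(), rel=0.01)

    def test_zero_area_rejected(self, coarse_talon):
        _, tet, _ = coarse_talon
        with pytest.raises(ValueError):
            scale_to_reference_area(tet, 0.0)


class TestSolve:
    def test_zero_load_zero_field(self):
        m = structured_box_mesh(2, 2, 4, 1, 1, 2)
        case = LoadCase(restraints=[("z0", "xyz")], loads=[])
        field = solve(apply_load_case(m, case))
        assert np.abs(field.displacements).max() == 0.0
        assert np.abs(field.vm_stress).max() == 0.0

    def test_uniaxial_patch_test(self):
        m = uniaxial_bar(2)
        case = LoadCase(restraints=[("z0", "z"), ("pin_xy", "xy"), ("pin_y", "y")],
                        loads=[])
        system = apply_load_case(m, case)
        system.f = end_traction(m, 7.0)
        field = solve(system)
        np.testing.assert_allclose(field.vm_stress, 7.0, rtol=1e-6)

    def test_reaction_equilibrium(self):
        m = uniaxial_bar(2)
        case = LoadCase(restraints=[("z0", "z"), ("pin_xy", "xy"), ("pin_y", "y")],
                        loads=[])
        system = apply_load_case(m, case)
        system.f = end_traction(m, 7.0)
        field = solve(system)
        total = field.reactions.sum(axis=0) + [0, 0, 7.0]
        assert np.abs(total).max() < 1e-8 * 7.0

    def test_stiffness_scaling_linearity(self, coarse_talon):
        _, tet, _ = coarse_talon
        case = grip_load_case()
        f1 = solve(apply_load_case(tet, case, BONE))
        stiff = ElasticMaterial(2 * BONE.youngs_modulus, BONE.poisson_ratio)
        f2 = solve(apply_load_case(tet, case, stiff))
        np.testing.assert_allclose(f2.displacements, f1.displacements / 2,
                                   atol=1e-9 * np.abs(f1.displacements).max())
        np.testing.assert_allclose(f2.vm_stress, f1.vm_stress,
                                   rtol=1e-9)

    def test_cg_matches_direct(self):
        m = uniaxial_bar(2)
        case = LoadCase(restraints=[("z0", "z"), ("pin_xy", "xy"), ("pin_y", "y")],
                        loads=[])
        system = apply_load_case(m, case)
        system.f = end_traction(m, 3.0)
        ud = solve(system, method="direct").displacements
        uc = solve(system, method="cg").displacements
        np.testing.assert_allclose(uc, ud, atol=1e-8 * np.abs(ud).max())

    def test_missing_restraints_rejected(self):
        m = structured_box_mesh(2, 2, 4, 1, 1, 2)
        with pytest.raises(ValueError, match="rigid-body"):
            apply_load_case(m, LoadCase(restraints=[], loads=[]))


class TestGripProtocol:
    def test_per_digit_force_arithmetic(self):
        case = grip_load_case(9.77, 4)
        per_patch = [np.asarray(f) for _, f in case.loads]
        total = sum(p for p in per_patch)
        # one digit's share, split over two tubercle patches, along -z
        np.testing.assert_allclose(total, [0, 0, -9.77 / 4], atol=1e-12)
        np.testing.assert_allclose(per_patch[0], [0, 0, -1.22125], atol=1e-12)

    def test_patch_load_uniformly_distributed(self, coarse_talon):
        _, tet, _ = coarse_talon
        case = grip_load_case()
        system = apply_load_case(tet, case)
        med = tet.node_sets["tubercle_medial"]
        fz = system.f[3 * med + 2]
        np.testing.assert_allclose(fz, -1.22125 / len(med), atol=1e-12)

    def test_scale_free_protocol(self, coarse_talon):
        _, tet, _ = coarse_talon
        ref_area = tet.surface_area()
        f1, _ = solve_grip(tet, reference_area=ref_area)
        f2, _ = solve_grip(tet.scaled(3.0), reference_area=ref_area)
        np.testing.assert_allclose(f2.vm_stress, f1.vm_stress,
                                   rtol=1e-8)

    def test_stiff_patch_mode_changes_solution_little(self, coarse_talon):
        _, tet, _ = coarse_talon
        f1 = solve(apply_load_case(tet, grip_load_case()))
        f2 = solve(apply_load_case(tet, grip_load_case(stiff_patch=True)))
        # stiffener spreads the local load; global response stays comparable
        assert np.abs(f2.displacements).max() <= np.abs(f1.displacements).max() * 1.5
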