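"""Plane-stress solver: element stiffness, constraints, analytic oracles."""

import math

import numpy as np
import pytest

from plexusfem.errors import RankDeficiencyError
from plexusfem.fixtures import make_bar_fixture, make_patch_fixture
from plexusfem.meshing import rect_mesh
from plexusfem.solver import (BoundaryConditions, MaterialProperties,
                              assemble_and_solve, element_stiffness,
                              tri_stiffness, von_mises_plane_stress)

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
MAT = MaterialProperties(1.0, 0.0)


def brute_force_quad_stiffness(coords, material, n_gauss=4):
    """Independent oracle: numerically integrated B^T D B with high-order
    Gauss quadrature, assembled from first principles."""
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    d = material.d_matrix
    k = np.zeros((8, 8))
    for xi, wx in zip(pts, wts):
        for eta, wy in zip(pts, wts):
            dn = 0.25 * np.array([
                [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
                [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)],
            ])
            jac = dn @ coords
            det = np.linalg.det(jac)
            dndx = np.linalg.solve(jac, dn)
            b = np.zeros((3, 8))
            b[0, 0::2] = dndx[0]
            b[1, 1::2] = dndx[1]
            b[2, 0::2] = dndx[1]
            b[2, 1::2] = dndx[0]
            k += wx * wy * b.T @ d @ b * det * material.thickness
    return k


def _zero_eigs(k, tol=1e-9):
    ev = np.linalg.eigvalsh(k)
    return int((np.abs(ev) < tol * np.abs(ev).max()).sum())


def test_stiffness_symmetry():
    coords = np.array([[0.0, 0.0], [2.1, 0.2], [1.9, 1.3], [-0.1, 1.1]])
    for scheme in ("full_2x2", "reduced_1pt"):
        k = element_stiffness(coords, MAT, scheme)
        assert np.max(np.abs(k - k.T)) == 0.0


def test_full_integration_has_exactly_three_rigid_body_modes():
    assert _zero_eigs(element_stiffness(UNIT_SQUARE, MAT, "full_2x2")) == 3


def test_reduced_integration_hourglass_modes_and_stabilisation():
    k_raw = element_stiffness(UNIT_SQUARE, MAT, "reduced_1pt",
                              hourglass=False)
    assert _zero_eigs(k_raw) == 5      # 3 rigid-body + 2 hourglass
    k_stab = element_stiffness(UNIT_SQUARE, MAT, "reduced_1pt",
                               hourglass=True)
    assert _zero_eigs(k_stab) == 3


def test_rigid_translation_produces_zero_force():
    k = element_stiffness(UNIT_SQUARE, MAT, "full_2x2")
    tx = np.tile([1.0, 0.0], 4)
    assert np.abs(k @ tx).max() < 1e-12


def test_unit_square_stiffness_matches_brute_force_oracle():
    k = element_stiffness(UNIT_SQUARE, MAT, "full_2x2")
    k_ref = brute_force_quad_stiffness(UNIT_SQUARE, MAT)
    assert np.allclose(k, k_ref, atol=1e-12)


def test_distorted_quad_stiffness_matches_high_order_quadrature():
    # bilinear quads with constant-Jacobian-free distortion still
    # integrate exactly at 2x2 points only for parallelograms; compare
    # against 6-point quadrature on a parallelogram
    coords = np.array([[0.0, 0.0], [2.0, 0.3], [2.5, 1.5], [0.5, 1.2]])
    mat = MaterialProperties(1.48, 0.4)
    k = element_stiffness(coords, mat, "full_2x2")
    k_ref = brute_force_quad_stiffness(coords, mat, n_gauss=6)
    assert np.allclose(k, k_ref, atol=1e-10)


def test_tri_stiffness_rigid_body_modes():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])
    k = tri_stiffness(coords, MAT)
    assert np.max(np.abs(k - k.T)) < 1e-15
    assert _zero_eigs(k) == 3


@pytest.mark.parametrize("s,expected", [
    ((0.332, 0.0, 0.0), 0.332),            # uniaxial
    ((0.7, 0.7, 0.0), 0.7),                # equibiaxial
    ((1.0, -1.0, 0.0), math.sqrt(3.0)),    # pure shear-like state
    ((0.0, 0.0, 0.0), 0.0),
])
def test_von_mises_plane_stress_values(s, expected):
    assert von_mises_plane_stress(*s) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("scheme", ["full_2x2", "reduced_1pt"])
def test_patch_test_exact(scheme):
    fx = make_patch_fixture(distortion_seed=3)
    sol, stress = fx.solve(scheme)
    u_err = np.abs(sol.displacements
                   - fx.expected_displacement(fx.mesh.nodes)).max()
    assert u_err < 1e-10
    assert np.abs(stress.centroid - fx.expected_stress).max() < 1e-10


def test_patch_stress_constant_for_any_distortion():
    # the interior stress is determined by the imposed field alone,
    # independent of how the patch is distorted
    for seed in (1, 2):
        fx = make_patch_fixture(seed)
        _, stress = fx.solve()
        spread = stress.centroid.max(axis=0) - stress.centroid.min(axis=0)
        assert np.abs(spread).max() < 1e-10


def test_uniform_bar_closed_form():
    fx = make_bar_fixture(41.4, 3.0, 1.48, 0.0, 0.332, h=1.0)
    sol, stress = fx.solve()
    assert np.allclose(stress.centroid[:, 0], 0.332, rtol=1e-8)
    assert np.abs(stress.centroid[:, 1:]).max() < 1e-10
    assert np.allclose(stress.von_mises_centroid, 0.332, rtol=1e-8)
    right = fx.mesh.edge_set_nodes("right")
    u_end = sol.displacements[right, 0].mean()
    assert u_end == pytest.approx(0.332 * 41.4 / 1.48, rel=1e-8)
    assert sol.equilibrium_residual < 1e-8


def test_linearity_under_pressure_scaling():
    fx1 = make_bar_fixture(10.0, 2.0, 2.0, 0.3, 0.1, h=0.5)
    fx2 = make_bar_fixture(10.0, 2.0, 2.0, 0.3, 0.3, h=0.5)
    s1, st1 = fx1.solve()
    s2, st2 = fx2.solve()
    assert np.allclose(s2.displacements, 3.0 * s1.displacements, atol=1e-12)
    assert np.allclose(st2.centroid, 3.0 * st1.centroid, atol=1e-12)


def test_solution_invariant_under_rigid_translation():
    fx = make_bar_fixture(10.0, 2.0, 2.0, 0.4, 0.2, h=0.5)
    _, st = fx.solve()
    mesh2 = rect_mesh(10.0, 2.0, h=0.5)
    mesh2.nodes = mesh2.nodes + np.array([13.0, -7.0])
    bcs = BoundaryConditions()
    bcs.fix_nodes(mesh2.edge_set_nodes("left"))
    bcs.add_normal_pressure(mesh2, "right", 0.2, (1.0, 0.0))
    _, st2 = assemble_and_solve(mesh2, fx.material, bcs)
    assert np.allclose(st2.von_mises_centroid, st.von_mises_centroid,
                       rtol=1e-6)


def test_cantilever_tip_deflection_matches_beam_theory():
    # 10x1 cantilever, tip shear load; Timoshenko beam with shear
    # correction as the independent oracle
    length, depth, e_mod, nu, p = 10.0, 1.0, 100.0, 0.3, 0.01
    mesh = rect_mesh(length, depth, h=0.125)
    bcs = BoundaryConditions()
    bcs.fix_nodes(mesh.edge_set_nodes("left"))
    bcs.add_normal_pressure(mesh, "right", p, (0.0, 1.0))
    mat = MaterialProperties(e_mod, nu)
    sol, _ = assemble_and_solve(mesh, mat, bcs)
    tip = sol.displacements[mesh.edge_set_nodes("right"), 1].mean()
    force = p * depth
    inertia = depth ** 3 / 12.0
    g_mod = e_mod / (2 * (1 + nu))
    shear_area = 5.0 / 6.0 * depth
    expected = force * length ** 3 / (3 * e_mod * inertia) \
        + force * length / (g_mod * shear_area)
    assert tip == pytest.approx(expected, rel=0.05)


def test_guided_constraint_enforces_zero_normal_displacement():
    mesh = rect_mesh(10.0, 2.0, h=0.5)
    bcs = BoundaryConditions()
    bcs.fix_nodes(mesh.edge_set_nodes("left"))
    normal = (1.0, 1.0)
    fixed = set(int(n) for n in mesh.edge_set_nodes("left"))
    top = np.array([int(n) for n in mesh.edge_set_nodes("top")
                    if int(n) not in fixed])
    bcs.guide_nodes(top, normal)
    bcs.add_normal_pressure(mesh, "right", 0.2, (1.0, 0.0))
    sol, _ = assemble_and_solve(mesh, MaterialProperties(2.0, 0.3), bcs)
    n = np.asarray(normal) / np.linalg.norm(normal)
    assert np.abs(sol.displacements[top] @ n).max() < 1e-10
    assert sol.equilibrium_residual < 1e-8


def test_unconstrained_system_raises_rank_deficiency():
    mesh = rect_mesh(4.0, 2.0, h=1.0)
    bcs = BoundaryConditions()
    bcs.add_normal_pressure(mesh, "right", 0.1, (1.0, 0.0))
    with pytest.raises(RankDeficiencyError):
        assemble_and_solve(mesh, MaterialProperties(1.0, 0.0), bcs)


def test_prescribed_and_guided_conflict_rejected():
    mesh = rect_mesh(4.0, 2.0, h=1.0)
    bcs = BoundaryConditions()
    left = mesh.edge_set_nodes("left")
    bcs.fix_nodes(left)
    bcs.guide_nodes([int(left[0])], (0.0, 1.0))
    bcs.add_normal_pressure(mesh, "right", 0.1, (1.0, 0.0))
    with pytest.raises(ValueError):
        assemble_and_solve(mesh, MaterialProperties(1.0, 0.0), bcs)
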