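"""Verification fixtures: analytic oracles and randomized geometries."""

import numpy as np
import pytest

import plexusfem as pf
from plexusfem.anatomy import ROOT_IDS
from plexusfem.fixtures import (make_bar_fixture, make_patch_fixture,
                                random_plexus)
from plexusfem.postprocess import nodal_averaged_von_mises
from plexusfem.study import solve_case


def test_bar_fixture_closed_form_fields():
    fx = make_bar_fixture(41.4, 3.0, 1.48, 0.0, 0.332)
    sol, stress = fx.solve()
    u_err = np.abs(sol.displacements
                   - fx.expected_displacement(fx.mesh.nodes)).max()
    assert u_err < 1e-8
    assert np.allclose(stress.von_mises_centroid, 0.332, rtol=1e-8)
    # end displacement comparable in magnitude to the plexus prediction
    assert fx.expected_displacement(np.array([[41.4, 0.0]]))[0, 0] == \
        pytest.approx(9.29, abs=0.01)


def test_bar_fixture_zero_pressure_gives_zero_fields():
    fx = make_bar_fixture(10.0, 2.0, 1.0, 0.0, 0.0)
    sol, stress = fx.solve()
    assert np.abs(sol.displacements).max() < 1e-14
    assert np.abs(stress.von_mises_centroid).max() < 1e-14


def test_patch_fixture_self_consistency():
    fx = make_patch_fixture(0)
    # the imposed closed form satisfies the fixture's own BCs exactly
    for (nid, comp), val in fx.bcs.prescribed.items():
        assert fx.expected_displacement(fx.mesh.nodes[nid])[0, comp] == \
            pytest.approx(val, abs=1e-15)


def test_patch_fixture_zero_strain_field_gives_zero_stress():
    fx = make_patch_fixture(0)
    # replace prescribed values with a rigid translation
    for (nid, comp) in list(fx.bcs.prescribed):
        fx.bcs.prescribed[(nid, comp)] = 0.25 if comp == 0 else -0.1
    sol, stress = fx.solve()
    assert np.abs(stress.centroid).max() < 1e-12


def test_random_plexus_zero_jitter_is_baseline(config):
    base = config.build_geometry()
    g = random_plexus(seed=5, angle_jitter=0.0, length_jitter_fraction=0.0,
                      config=config)
    for rid in ROOT_IDS:
        assert np.array_equal(g.roots[rid].corners, base.roots[rid].corners)


def test_random_plexus_seed_determinism(config):
    g1 = random_plexus(seed=42, angle_jitter=3.0, config=config)
    g2 = random_plexus(seed=42, angle_jitter=3.0, config=config)
    for rid in ROOT_IDS:
        assert np.array_equal(g1.roots[rid].corners, g2.roots[rid].corners)
    g3 = random_plexus(seed=43, angle_jitter=3.0, config=config)
    assert not all(np.array_equal(g1.roots[r].corners, g3.roots[r].corners)
                   for r in ROOT_IDS)


@pytest.mark.parametrize("seed", range(8))
def test_random_plexus_pipeline_smoke(config, seed):
    """Jittered anatomies mesh and solve without error and keep their
    root path lengths."""
    g = random_plexus(seed=seed, angle_jitter=4.0,
                      length_jitter_fraction=0.05, config=config)
    for rid in ROOT_IDS:
        nominal = g.dims[rid].total_length
        assert g.roots[rid].length == pytest.approx(nominal, abs=1e-9)
    mesh = pf.generate_mesh(g, config.mesh.h_max, config.mesh.h_min)
    sol, stress = solve_case(g, mesh, config.load_cases["case1"],
                             guided_fraction=config.guided_edge_fraction)
    assert sol.equilibrium_residual < 1e-8
    assert np.isfinite(stress.von_mises_centroid).all()


def test_bar_mesh_convergence_at_reference_sizes():
    """Clamped-end bar at nu = 0.4: the junction stress away from the
    corners changes by < 2% between the reference mesh size and one
    uniform refinement."""
    vals = []
    for h in (2.0, 1.0):
        fx = make_bar_fixture(41.4, 3.0, 1.48, 0.4, 0.332, h=h)
        _, stress = fx.solve()
        left = fx.mesh.edge_set_nodes("left")
        ys = fx.mesh.nodes[left, 1]
        interior = left[(ys > 1e-9) & (ys < 3.0 - 1e-9)]
        vals.append(float(
            nodal_averaged_von_mises(stress, fx.mesh, interior).max()))
    assert abs(vals[1] - vals[0]) / vals[0] < 0.02


def test_random_plexus_reports_failure_after_resampling(config):
    with pytest.raises(pf.GeometryInfeasibleError):
        random_plexus(seed=0, angle_jitter=60.0, config=config,
                      max_resample=3)
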