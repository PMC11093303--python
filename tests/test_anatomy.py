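"""Geometry construction: path lengths, determinism, perturbation."""

import numpy as np
import pytest
from shapely import wkt as shapely_wkt

import plexusfem as pf
from plexusfem.anatomy import (ROOT_IDS, CordParameters,
                               DEFAULT_ROOT_DIMENSIONS, RootDimensions)
from plexusfem.errors import GeometryInfeasibleError

# cord-to-trunk path totals (mm): root segment sums plus trunk lengths
PATH_TOTALS = {"upper": 41.4, "middle": 38.3, "lower": 30.8}
ROOT_SUMS = {"C5": 30.5, "C6": 31.0, "C7": 33.5, "C8": 20.0, "T1": 13.5}


def test_root_segment_sums():
    for rid, total in ROOT_SUMS.items():
        assert DEFAULT_ROOT_DIMENSIONS[rid].total_length == pytest.approx(total)


def test_default_dimensions_shape_invariants():
    for rid in ROOT_IDS:
        d = DEFAULT_ROOT_DIMENSIONS[rid]
        assert d.d_cranial_caudal >= d.d_transverse
    assert DEFAULT_ROOT_DIMENSIONS["T1"].len_drg_to_foramen is None
    assert len(DEFAULT_ROOT_DIMENSIONS["T1"].segment_lengths) == 2


@pytest.mark.parametrize("trunk,total", sorted(PATH_TOTALS.items()))
def test_path_lengths_match_reported_totals(geometry, trunk, total):
    assert pf.path_length(geometry, trunk) == pytest.approx(total, abs=1e-9)


def test_root_paths_have_anatomical_lengths(geometry):
    for rid in ROOT_IDS:
        strip = geometry.roots[rid]
        assert strip.length == pytest.approx(ROOT_SUMS[rid], abs=1e-9)


def test_rebuild_is_bitwise_deterministic(config, geometry):
    again = config.build_geometry()
    for rid in ROOT_IDS:
        assert np.array_equal(geometry.roots[rid].corners,
                              again.roots[rid].corners)
    for tid in pf.TRUNK_IDS:
        assert np.array_equal(geometry.trunks[tid].corners,
                              again.trunks[tid].corners)


def test_perturb_zero_delta_is_identity(geometry):
    same = pf.perturb_root_angles(geometry, 0.0)
    for rid in ROOT_IDS:
        assert np.array_equal(geometry.roots[rid].corners,
                              same.roots[rid].corners)


def test_perturb_round_trip_recovers_angles(geometry):
    there = pf.perturb_root_angles(geometry, 6.0)
    back = pf.perturb_root_angles(there, -6.0)
    for rid in ROOT_IDS:
        assert back.root_angles[rid] == pytest.approx(
            geometry.root_angles[rid], abs=1e-9)


@pytest.mark.parametrize("delta", [-6.0, -3.0, 3.0, 6.0])
def test_perturbation_preserves_root_path_lengths(geometry, delta):
    pert = pf.perturb_root_angles(geometry, delta)
    for rid in ROOT_IDS:
        assert pert.roots[rid].length == pytest.approx(
            geometry.roots[rid].length, abs=1e-9)
        assert pert.root_angles[rid] == pytest.approx(
            geometry.root_angles[rid] + delta)


def test_perturb_rejects_delta_outside_safe_range(geometry):
    with pytest.raises(ValueError):
        pf.perturb_root_angles(geometry, 12.0)


def test_strip_width_constant_along_each_root(geometry):
    # perpendicular distance between the lateral edge lines equals the
    # cranial-caudal diameter
    for rid in ROOT_IDS:
        strip = geometry.roots[rid]
        c = strip.corners
        top_dir = c[1] - c[0]
        top_dir = top_dir / np.linalg.norm(top_dir)
        rel = c[3] - c[0]  # prox-caudal corner relative to prox-cranial
        dist = abs(rel[0] * top_dir[1] - rel[1] * top_dir[0])
        assert dist == pytest.approx(strip.width, rel=1e-9)


def test_trunk_face_tiled_exactly_by_member_roots(geometry):
    for tid, members in pf.TRUNK_MEMBERS.items():
        trunk = geometry.trunks[tid]
        total = sum(np.linalg.norm(geometry.roots[m].dist_face[0]
                                   - geometry.roots[m].dist_face[1])
                    for m in members)
        assert trunk.width == pytest.approx(total, rel=1e-9)
        # member faces are collinear with the trunk face endpoints
        for m in members:
            for p in geometry.roots[m].dist_face:
                v = p - trunk.prox_face[0]
                w = trunk.prox_face[1] - trunk.prox_face[0]
                assert abs(v[0] * w[1] - v[1] * w[0]) < 1e-6


def test_domain_is_single_connected_polygon(geometry):
    from shapely.ops import unary_union
    dom = unary_union([p.buffer(1e-6)
                       for p in geometry.region_polygons().values()])
    assert dom.geom_type == "Polygon"


def test_wkt_export_round_trips(geometry):
    geom = shapely_wkt.loads(geometry.to_wkt())
    assert geom.geom_type == "GeometryCollection"
    assert len(geom.geoms) == 9  # cord + 5 roots + 3 trunks


def test_svg_export_contains_all_regions(geometry):
    svg = geometry.to_svg()
    assert svg.count("<polygon") == 9
    assert "root:C5" in svg and "trunk:lower" in svg


def test_overlapping_attachments_name_the_offending_pair(config):
    cord = CordParameters(config.cord.cord_width, config.cord.cord_length,
                          (6.0, 7.0, 19.4, 28.6, 36.2))  # C5/C6 too close
    with pytest.raises(GeometryInfeasibleError, match="C5.*C6"):
        pf.build_baseline_geometry(config.dims, cord, config.root_angles,
                                   config.trunk_lengths, config.trunk_angles)


def test_diverging_pair_is_rejected(config):
    angles = dict(config.root_angles)
    angles["C6"] = angles["C5"] - 5.0  # C6 aims away from C5: no merge
    with pytest.raises(GeometryInfeasibleError):
        pf.build_baseline_geometry(config.dims, config.cord, angles,
                                   config.trunk_lengths, config.trunk_angles)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        RootDimensions("C5", -1.0, 1.0, 7.5, 9.0, 14.0)
    with pytest.raises(ValueError):
        CordParameters(7.0, 42.0, (6.0, 5.0, 19.0, 28.0, 36.0))
    with pytest.raises(ValueError):
        CordParameters(7.0, 30.0, (6.0, 12.0, 19.0, 28.0, 36.0))
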