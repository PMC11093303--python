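"""Analytic verification fixtures and randomized geometry generators.

Every pipeline stage is testable without external data: a uniform bar
with a closed-form uniaxial solution, a distorted-quad patch under an
imposed linear displacement field (constant-stress patch test), and
seeded random perturbations of the baseline plexus anatomy emulating the
individual variability of nerve-root angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .anatomy import ROOT_IDS, PlexusGeometry, RootDimensions, \
    build_baseline_geometry
from .config import PlexusConfig, load_config
from .errors import GeometryInfeasibleError
from .meshing import Mesh, rect_mesh
from .solver import (BoundaryConditions, MaterialProperties, Solution,
                     StressField, assemble_and_solve)


@dataclass
class AnalyticFixture:
    """A mesh + BC problem with a known closed-form solution."""

    name: str
    mesh: Mesh
    material: MaterialProperties
    bcs: BoundaryConditions
    expected_displacement: Callable[[np.ndarray], np.ndarray]
    expected_stress: np.ndarray     # (3,) constant [sxx, syy, sxy]
    tolerance: float
    exact: bool                     # closed form lies in the FE space

    def solve(self, scheme: str = "full_2x2") -> tuple[Solution, StressField]:
        return assemble_and_solve(self.mesh, self.material, self.bcs, scheme)


def make_bar_fixture(length: float, width: float, youngs_modulus: float,
                     poisson_ratio: float, pressure: float,
                     h: float = 1.0) -> AnalyticFixture:
    """Clamped-end bar under uniform end traction.

    The left edge is encastre and a uniform normal pressure pulls on the
    right edge.  For ``poisson_ratio == 0`` the exact solution is the
    uniform uniaxial state sxx = p, u_x = p x / E (contained in the
    bilinear element space, so the FE answer is exact to solver
    precision).  For nonzero Poisson ratio the clamped end perturbs the
    field locally and the fixture serves mesh-convergence studies.
    """
    mesh = rect_mesh(length, width, h=h)
    mat = MaterialProperties(youngs_modulus, poisson_ratio)
    bcs = BoundaryConditions()
    bcs.fix_nodes(mesh.edge_set_nodes("left"))
    bcs.add_normal_pressure(mesh, "right", pressure, (1.0, 0.0))

    def u_exact(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        out = np.zeros_like(pts, dtype=float)
        out[:, 0] = pressure * pts[:, 0] / youngs_modulus
        out[:, 1] = -poisson_ratio * pressure * pts[:, 1] / youngs_modulus
        return out

    return AnalyticFixture(
        "uniform_bar", mesh, mat, bcs, u_exact,
        np.array([pressure, 0.0, 0.0]),
        tolerance=1e-8, exact=(poisson_ratio == 0.0))


def make_patch_fixture(distortion_seed: int = 0,
                       youngs_modulus: float = 1.48,
                       poisson_ratio: float = 0.4) -> AnalyticFixture:
    """Five distorted quads in a unit square under an imposed linear field.

    The boundary (corner) nodes carry prescribed displacements from a
    random linear field u = a + b x + c y; a correct bilinear element
    must reproduce the field and its constant stress exactly (patch
    test).  The seed jitters both the interior node positions and the
    field coefficients.
    """
    rng = np.random.default_rng(distortion_seed)
    outer = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    inner = np.array([[0.30, 0.28], [0.72, 0.22], [0.78, 0.74], [0.24, 0.70]])
    inner = inner + rng.uniform(-0.05, 0.05, size=inner.shape)

    from .meshing import _Builder  # shared node bookkeeping
    b = _Builder()
    o = [b.node(p) for p in outer]
    i = [b.node(p) for p in inner]
    for k in range(4):
        kn = (k + 1) % 4
        b.quads.append((o[k], o[kn], i[kn], i[k]))
        b.quad_tags.append("patch")
    b.quads.append((i[0], i[1], i[2], i[3]))
    b.quad_tags.append("patch")
    mesh = b.build()

    coeffs = rng.uniform(-0.5, 0.5, size=6)  # a1 b1 c1 a2 b2 c2
    a1, b1, c1, a2, b2, c2 = coeffs

    def u_exact(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return np.column_stack([a1 + b1 * pts[:, 0] + c1 * pts[:, 1],
                                a2 + b2 * pts[:, 0] + c2 * pts[:, 1]])

    mat = MaterialProperties(youngs_modulus, poisson_ratio)
    strain = np.array([b1, c2, b2 + c1])
    bcs = BoundaryConditions()
    for nid in o:
        ux, uy = u_exact(mesh.nodes[nid])[0]
        bcs.prescribed[(nid, 0)] = float(ux)
        bcs.prescribed[(nid, 1)] = float(uy)
    return AnalyticFixture("patch", mesh, mat, bcs, u_exact,
                           mat.d_matrix @ strain, tolerance=1e-10, exact=True)


def random_plexus(seed: int, angle_jitter: float = 3.0,
                  length_jitter_fraction: float = 0.0,
                  config: PlexusConfig | None = None,
                  max_resample: int = 20) -> PlexusGeometry:
    """Seeded random variant of the baseline plexus anatomy.

    Root angles are jittered uniformly within ``+-angle_jitter`` degrees
    and segment lengths scaled within ``+-length_jitter_fraction``;
    infeasible draws are resampled up to ``max_resample`` times.  Zero
    jitter reproduces the baseline geometry exactly.
    """
    cfg = config if config is not None else load_config()
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for _ in range(max_resample):
        angles = {rid: cfg.root_angles[rid]
                  + rng.uniform(-angle_jitter, angle_jitter)
                  for rid in ROOT_IDS}
        dims = {}
        for rid in ROOT_IDS:
            d = cfg.dims[rid]
            s = 1.0 + rng.uniform(-length_jitter_fraction,
                                  length_jitter_fraction)
            dims[rid] = RootDimensions(
                rid, d.d_cranial_caudal, d.d_transverse,
                d.len_spinal_to_drg * s,
                None if d.len_drg_to_foramen is None
                else d.len_drg_to_foramen * s,
                d.len_foramen_to_trunk * s)
        try:
            return build_baseline_geometry(dims, cfg.cord, angles,
                                           cfg.trunk_lengths,
                                           cfg.trunk_angles)
        except GeometryInfeasibleError as exc:
            last_err = exc
    raise GeometryInfeasibleError(
        f"no feasible geometry after {max_resample} draws "
        f"(seed {seed}): {last_err}")
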