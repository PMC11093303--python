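"""Plane-stress linear-elastic finite-element solver.

Elements are isoparametric 4-node bilinear quadrilaterals (full 2x2
Gauss integration by default; single-point reduced integration with
stiffness-type hourglass stabilisation behind a flag) and 3-node
constant-strain triangles.  Unit thickness is assumed, so an edge
"pressure" in MPa is a line traction in N/mm and reported stresses are
thickness-independent.

Boundary conditions support prescribed displacement components
(encastre = both components zero), skew "guided" constraints n.u = 0
enforced with Lagrange multipliers (used for the symmetry-type supports
on the outermost nerve edges), and consistent nodal loads from uniform
edge tractions.  The linear solve is a deterministic sparse direct
factorisation; every solve records its global equilibrium residual.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import RankDeficiencyError, SolverError
from .meshing import Mesh, tri_area

_GP = 1.0 / math.sqrt(3.0)
_QUAD_GAUSS_2x2 = [(-_GP, -_GP), (_GP, -_GP), (_GP, _GP), (-_GP, _GP)]
#: dimensionless stiffness coefficient for hourglass stabilisation
HOURGLASS_COEFF = 0.01


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic linear-elastic plane-stress material (MPa, mm)."""

    youngs_modulus: float
    poisson_ratio: float
    thickness: float = 1.0

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")

    @property
    def d_matrix(self) -> np.ndarray:
        e, nu = self.youngs_modulus, self.poisson_ratio
        return e / (1 - nu * nu) * np.array([
            [1.0, nu, 0.0],
            [nu, 1.0, 0.0],
            [0.0, 0.0, (1 - nu) / 2.0],
        ])


@dataclass
class BoundaryConditions:
    """Prescribed displacements, guided (skew) constraints, edge tractions."""

    #: (node id, component 0|1) -> prescribed displacement value (mm)
    prescribed: dict[tuple[int, int], float] = field(default_factory=dict)
    #: (node id, unit constraint direction): enforces n . u = 0
    guided: list[tuple[int, tuple[float, float]]] = field(default_factory=list)
    #: (node a, node b, tx, ty): uniform traction vector (MPa) on the edge
    edge_tractions: list[tuple[int, int, float, float]] = field(default_factory=list)

    def fix_nodes(self, node_ids, value: tuple[float, float] = (0.0, 0.0)):
        """Encastre: prescribe both displacement components on the nodes."""
        for n in node_ids:
            self.prescribed[(int(n), 0)] = float(value[0])
            self.prescribed[(int(n), 1)] = float(value[1])
        return self

    def guide_nodes(self, node_ids, normal):
        """Fix the displacement component along ``normal`` on the nodes."""
        nv = np.asarray(normal, dtype=float)
        nv = nv / np.linalg.norm(nv)
        for n in node_ids:
            self.guided.append((int(n), (float(nv[0]), float(nv[1]))))
        return self

    def add_normal_pressure(self, mesh: Mesh, edge_set: str, pressure: float,
                            direction):
        """Uniform pressure (MPa) pulling along ``direction`` on a named
        edge set (the outward normal of the loaded face)."""
        dv = np.asarray(direction, dtype=float)
        dv = dv / np.linalg.norm(dv)
        for a, b in mesh.edge_sets[edge_set]:
            self.edge_tractions.append(
                (int(a), int(b), float(pressure * dv[0]), float(pressure * dv[1])))
        return self


@dataclass
class Solution:
    """Nodal displacements (mm), reaction forces (N) and solve diagnostics."""

    displacements: np.ndarray       # (N, 2)
    reactions: np.ndarray           # (N, 2), nonzero only at constrained dofs
    equilibrium_residual: float     # |sum reactions + sum applied| / |applied|


@dataclass
class StressField:
    """Per-element stresses (MPa): centroid tensor components, centroid von
    Mises, and the maximum von Mises over the element's Gauss points."""

    centroid: np.ndarray            # (n_el, 3): sxx, syy, sxy
    von_mises_centroid: np.ndarray  # (n_el,)
    von_mises_max_gp: np.ndarray    # (n_el,)
    gauss: list[np.ndarray]         # per element, (n_gp, 3)


def von_mises_plane_stress(sxx, syy, sxy):
    """Equivalent (von Mises) stress for a plane-stress tensor."""
    sxx, syy, sxy = (np.asarray(v, dtype=float) for v in (sxx, syy, sxy))
    return np.sqrt(np.maximum(sxx * sxx - sxx * syy + syy * syy
                              + 3.0 * sxy * sxy, 0.0))


def _quad_b_matrix(coords: np.ndarray, xi: float, eta: float):
    """Strain-displacement matrix and Jacobian determinant at (xi, eta)."""
    dn = 0.25 * np.array([
        [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
        [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)],
    ])
    jac = dn @ coords
    det = jac[0, 0] * jac[1, 1] - jac[0, 1] * jac[1, 0]
    if det <= 0:
        raise SolverError("non-positive Jacobian in quadrilateral element")
    dndx = np.linalg.solve(jac, dn)
    b = np.zeros((3, 8))
    b[0, 0::2] = dndx[0]
    b[1, 1::2] = dndx[1]
    b[2, 0::2] = dndx[1]
    b[2, 1::2] = dndx[0]
    return b, det


def _hourglass_stiffness(coords: np.ndarray, material: MaterialProperties):
    """Stiffness-type hourglass control for the 1-point quad (gamma mode)."""
    x, y = coords[:, 0], coords[:, 1]
    a = 0.5 * ((x[1] - x[3]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[3]))
    bx = np.array([y[1] - y[3], y[2] - y[0], y[3] - y[1], y[0] - y[2]]) / (2 * a)
    by = np.array([x[3] - x[1], x[0] - x[2], x[1] - x[3], x[2] - x[0]]) / (2 * a)
    h = np.array([1.0, -1.0, 1.0, -1.0])
    gamma = 0.25 * (h - (h @ x) * bx - (h @ y) * by)
    k = np.zeros((8, 8))
    kappa = HOURGLASS_COEFF * material.youngs_modulus * material.thickness * a \
        * (bx @ bx + by @ by)
    outer = np.outer(gamma, gamma)
    k[0::2, 0::2] = kappa * outer
    k[1::2, 1::2] = kappa * outer
    return k


def element_stiffness(coords: np.ndarray, material: MaterialProperties,
                      scheme: str = "full_2x2",
                      hourglass: bool = True) -> np.ndarray:
    """8x8 stiffness of a bilinear quad (N/mm).

    ``full_2x2`` integrates exactly enough to leave only the three 2D
    rigid-body zero-energy modes; ``reduced_1pt`` has additional
    hourglass modes, removed by gamma-mode stabilisation unless
    ``hourglass=False``.
    """
    coords = np.asarray(coords, dtype=float)
    d = material.d_matrix
    t = material.thickness
    k = np.zeros((8, 8))
    if scheme == "full_2x2":
        for xi, eta in _QUAD_GAUSS_2x2:
            b, det = _quad_b_matrix(coords, xi, eta)
            k += b.T @ d @ b * det * t
    elif scheme == "reduced_1pt":
        b, det = _quad_b_matrix(coords, 0.0, 0.0)
        k += b.T @ d @ b * det * t * 4.0
        if hourglass:
            k += _hourglass_stiffness(coords, material)
    else:
        raise ValueError(f"unknown integration scheme {scheme!r}")
    return k


def _tri_b_matrix(coords: np.ndarray):
    a = tri_area(coords)
    if a <= 0:
        raise SolverError("non-positive area in triangular element")
    x, y = coords[:, 0], coords[:, 1]
    bvec = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]]) / (2 * a)
    cvec = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]]) / (2 * a)
    b = np.zeros((3, 6))
    b[0, 0::2] = bvec
    b[1, 1::2] = cvec
    b[2, 0::2] = cvec
    b[2, 1::2] = bvec
    return b, a


def tri_stiffness(coords: np.ndarray, material: MaterialProperties) -> np.ndarray:
    """6x6 stiffness of a constant-strain triangle (N/mm)."""
    b, a = _tri_b_matrix(np.asarray(coords, dtype=float))
    return b.T @ material.d_matrix @ b * a * material.thickness


def _assemble(mesh: Mesh, material: MaterialProperties, scheme: str):
    ndof = 2 * mesh.n_nodes
    rows, cols, vals = [], [], []

    def _scatter(conn, ke):
        dofs = np.empty(2 * len(conn), dtype=np.int64)
        dofs[0::2] = 2 * np.asarray(conn)
        dofs[1::2] = 2 * np.asarray(conn) + 1
        r, c = np.meshgrid(dofs, dofs, indexing="ij")
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(ke.ravel())

    for conn in mesh.quads:
        _scatter(conn, element_stiffness(mesh.nodes[conn], material, scheme))
    for conn in mesh.tris:
        _scatter(conn, tri_stiffness(mesh.nodes[conn], material))
    k = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof)).tocsr()
    return k


def _traction_loads(mesh: Mesh, bcs: BoundaryConditions,
                    material: MaterialProperties) -> np.ndarray:
    f = np.zeros(2 * mesh.n_nodes)
    for a, b, tx, ty in bcs.edge_tractions:
        length = np.linalg.norm(mesh.nodes[b] - mesh.nodes[a])
        half = 0.5 * length * material.thickness
        f[2 * a] += half * tx
        f[2 * a + 1] += half * ty
        f[2 * b] += half * tx
        f[2 * b + 1] += half * ty
    return f


def assemble_and_solve(mesh: Mesh, material: MaterialProperties,
                       bcs: BoundaryConditions,
                       scheme: str = "full_2x2"):
    """Assemble, apply constraints and solve; return (Solution, StressField).

    Raises :class:`RankDeficiencyError` when the constraints leave
    rigid-body modes, :class:`SolverError` on non-finite results.
    """
    ndof = 2 * mesh.n_nodes
    k = _assemble(mesh, material, scheme)
    f = _traction_loads(mesh, bcs, material)

    prescribed_idx = np.array(
        [2 * n + c for (n, c) in bcs.prescribed], dtype=np.int64)
    prescribed_val = np.array(list(bcs.prescribed.values()), dtype=float)
    guided_nodes = {n for n, _ in bcs.guided}
    for (n, c) in bcs.prescribed:
        if n in guided_nodes:
            raise ValueError(
                f"node {n} is both prescribed and guided; resolve the conflict")
    if len(prescribed_idx) == 0 and not bcs.guided:
        raise RankDeficiencyError("no constraints given; rigid-body modes remain")

    mask_free = np.ones(ndof, dtype=bool)
    if len(prescribed_idx):
        mask_free[prescribed_idx] = False
    free = np.flatnonzero(mask_free)
    pos_in_free = -np.ones(ndof, dtype=np.int64)
    pos_in_free[free] = np.arange(len(free))

    u = np.zeros(ndof)
    if len(prescribed_idx):
        u[prescribed_idx] = prescribed_val
    rhs = f[free] - k[np.ix_(free, prescribed_idx)] @ prescribed_val \
        if len(prescribed_idx) else f[free].copy()
    kff = k[np.ix_(free, free)].tocsc()

    ng = len(bcs.guided)
    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            if ng:
                crows, ccols, cvals = [], [], []
                for i, (n, nv) in enumerate(bcs.guided):
                    for c in range(2):
                        j = pos_in_free[2 * n + c]
                        if j >= 0 and abs(nv[c]) > 0:
                            crows.append(i)
                            ccols.append(j)
                            cvals.append(nv[c])
                cmat = sp.coo_matrix((cvals, (crows, ccols)),
                                     shape=(ng, len(free))).tocsr()
                kkt = sp.bmat([[kff, cmat.T], [cmat, None]], format="csc")
                sol = spla.spsolve(kkt, np.concatenate([rhs, np.zeros(ng)]))
                u[free] = sol[:len(free)]
            else:
                u[free] = spla.spsolve(kff, rhs)
        except spla.MatrixRankWarning as exc:
            raise RankDeficiencyError(
                "constrained stiffness matrix is singular") from exc
    if not np.all(np.isfinite(u)):
        raise RankDeficiencyError(
            "solve produced non-finite displacements (singular system)")

    residual_forces = k @ u - f
    constrained = np.zeros(ndof, dtype=bool)
    if len(prescribed_idx):
        constrained[prescribed_idx] = True
    for n, _ in bcs.guided:
        constrained[2 * n] = True
        constrained[2 * n + 1] = True
    reactions = np.where(constrained, residual_forces, 0.0)
    total_reaction = np.array([reactions[0::2].sum(), reactions[1::2].sum()])
    total_applied = np.array([f[0::2].sum(), f[1::2].sum()])
    denom = max(np.abs(f).sum(), 1e-30)
    eq_res = float(np.linalg.norm(total_reaction + total_applied) / denom)

    solution = Solution(u.reshape(-1, 2), reactions.reshape(-1, 2), eq_res)
    stress = compute_stresses(mesh, material, solution, scheme)
    return solution, stress


def compute_stresses(mesh: Mesh, material: MaterialProperties,
                     solution: Solution, scheme: str = "full_2x2") -> StressField:
    """Element stress recovery: tensor at Gauss points and centroid, von
    Mises at both (triangles carry a single constant state)."""
    d = material.d_matrix
    u = solution.displacements
    centroid, vmc, vmg, gauss = [], [], [], []
    for conn in mesh.quads:
        coords = mesh.nodes[conn]
        ue = u[conn].ravel()
        gps = []
        for xi, eta in _QUAD_GAUSS_2x2:
            b, _ = _quad_b_matrix(coords, xi, eta)
            gps.append(d @ (b @ ue))
        gps = np.asarray(gps)
        b0, _ = _quad_b_matrix(coords, 0.0, 0.0)
        sc = d @ (b0 @ ue)
        centroid.append(sc)
        vmc.append(von_mises_plane_stress(*sc))
        vmg.append(von_mises_plane_stress(gps[:, 0], gps[:, 1], gps[:, 2]).max())
        gauss.append(gps)
    for conn in mesh.tris:
        b, _ = _tri_b_matrix(mesh.nodes[conn])
        sc = d @ (b @ u[conn].ravel())
        centroid.append(sc)
        vmc.append(von_mises_plane_stress(*sc))
        vmg.append(von_mises_plane_stress(*sc))
        gauss.append(sc[None, :])
    return StressField(np.asarray(centroid), np.asarray(vmc, dtype=float),
                       np.asarray(vmg, dtype=float), gauss)
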