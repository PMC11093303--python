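"""Quadrilateral meshing of the plexus domain.

Every region (cord, the five root strips, the three trunk strips) is a
four-sided patch and is meshed by transfinite (mapped) interpolation, so
the mesh is all-quad, deterministic and bit-reproducible.  Conformity at
the interfaces is obtained by construction rather than by search:

* the cord's axial node spacing includes the mitred root junction faces,
  whose node positions are computed once and shared with the root patches;
* each trunk's proximal cross-section is the concatenation of its member
  roots' distal face nodes (the merge point X is a shared node).

Node numbering is lexicographic by region (cord, roots C5..T1, trunks
upper/middle/lower) then by grid index; duplicate coordinates at region
interfaces are merged to a single node id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anatomy import ROOT_IDS, TRUNK_IDS, TRUNK_MEMBERS, PlexusGeometry
from .errors import MeshError

_GP = 1.0 / math.sqrt(3.0)
_QUAD_GAUSS = [(-_GP, -_GP), (_GP, -_GP), (_GP, _GP), (-_GP, _GP)]


@dataclass(frozen=True)
class MeshParams:
    """Global element-size bounds (mm)."""

    h_max: float = 2.0
    h_min: float = 0.2

    def __post_init__(self):
        if not 0 < self.h_min <= self.h_max:
            raise ValueError("require 0 < h_min <= h_max")


def refine(params: MeshParams, factor: float) -> MeshParams:
    """Uniformly refine the size bounds: divide h_max and h_min by ``factor``."""
    if factor < 1:
        raise ValueError("refinement factor must be >= 1")
    return MeshParams(params.h_max / factor, params.h_min / factor)


@dataclass
class Mesh:
    """Planar FE mesh: nodes, 4-node quads (plus optional 3-node triangles),
    per-element region tags and named boundary/interface edge sets."""

    nodes: np.ndarray                  # (N, 2) mm
    quads: np.ndarray                  # (nq, 4) node ids, counter-clockwise
    tris: np.ndarray                   # (nt, 3) node ids, counter-clockwise
    quad_tags: list[str]
    tri_tags: list[str]
    edge_sets: dict[str, list[tuple[int, int]]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.quads) + len(self.tris)

    def element_nodes(self, e: int) -> np.ndarray:
        """Connectivity of global element ``e`` (quads first, then triangles)."""
        nq = len(self.quads)
        return self.quads[e] if e < nq else self.tris[e - nq]

    def element_tag(self, e: int) -> str:
        nq = len(self.quads)
        return self.quad_tags[e] if e < nq else self.tri_tags[e - nq]

    @property
    def element_tags(self) -> list[str]:
        return list(self.quad_tags) + list(self.tri_tags)

    def edge_set_nodes(self, name: str) -> np.ndarray:
        """Unique node ids of a named edge set, in chain order."""
        edges = self.edge_sets[name]
        seen: dict[int, None] = {}
        for a, b in edges:
            seen.setdefault(a)
            seen.setdefault(b)
        return np.array(list(seen), dtype=np.int64)

    def edge_lengths(self) -> np.ndarray:
        """Lengths of all element edges (each edge counted once)."""
        seen = set()
        out = []
        for conn in list(self.quads) + list(self.tris):
            k = len(conn)
            for i in range(k):
                a, b = int(conn[i]), int(conn[(i + 1) % k])
                key = (min(a, b), max(a, b))
                if key not in seen:
                    seen.add(key)
                    out.append(np.linalg.norm(self.nodes[a] - self.nodes[b]))
        return np.asarray(out)

    def quad_fraction(self) -> float:
        return len(self.quads) / max(self.n_elements, 1)


def quad_jacobians(coords: np.ndarray) -> np.ndarray:
    """Jacobian determinants of a bilinear quad at its 2x2 Gauss points."""
    x, y = coords[:, 0], coords[:, 1]
    dets = []
    for xi, eta in _QUAD_GAUSS:
        dn = 0.25 * np.array([
            [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
            [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)],
        ])
        j = dn @ coords
        dets.append(np.linalg.det(j))
    return np.asarray(dets)


def tri_area(coords: np.ndarray) -> float:
    (x1, y1), (x2, y2), (x3, y3) = coords
    return 0.5 * ((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))


class _Builder:
    """Accumulates nodes (merging coincident coordinates) and elements."""

    def __init__(self):
        self.coords: list[tuple[float, float]] = []
        self._index: dict[tuple[float, float], int] = {}
        self.quads: list[tuple[int, int, int, int]] = []
        self.quad_tags: list[str] = []
        self.tris: list[tuple[int, int, int]] = []
        self.tri_tags: list[str] = []
        self.edge_sets: dict[str, list[tuple[int, int]]] = {}

    def node(self, p) -> int:
        key = (round(float(p[0]), 9), round(float(p[1]), 9))
        idx = self._index.get(key)
        if idx is None:
            idx = len(self.coords)
            self._index[key] = idx
            self.coords.append((float(p[0]), float(p[1])))
        return idx

    def grid(self, points: np.ndarray) -> np.ndarray:
        """Register an (ni, nj, 2) array of points; returns (ni, nj) node ids."""
        ni, nj = points.shape[:2]
        ids = np.empty((ni, nj), dtype=np.int64)
        for i in range(ni):
            for j in range(nj):
                ids[i, j] = self.node(points[i, j])
        return ids

    def quads_from_grid(self, ids: np.ndarray, tag: str):
        nodes = np.asarray(self.coords)
        ni, nj = ids.shape
        for i in range(ni - 1):
            for j in range(nj - 1):
                conn = (ids[i, j], ids[i, j + 1], ids[i + 1, j + 1], ids[i + 1, j])
                c = nodes[list(conn)]
                if quad_jacobians(c).min() <= 0:
                    conn = tuple(reversed(conn))
                    c = nodes[list(conn)]
                    if quad_jacobians(c).min() <= 0:
                        raise MeshError(
                            f"degenerate quad in region {tag!r} at grid ({i},{j})")
                self.quads.append(conn)
                self.quad_tags.append(tag)

    def chain_edges(self, name: str, node_ids):
        self.edge_sets.setdefault(name, []).extend(
            (int(a), int(b)) for a, b in zip(node_ids, node_ids[1:]))

    def build(self) -> Mesh:
        tris = (np.asarray(self.tris, dtype=np.int64)
                if self.tris else np.empty((0, 3), dtype=np.int64))
        return Mesh(np.asarray(self.coords), np.asarray(self.quads, dtype=np.int64),
                    tris, self.quad_tags, self.tri_tags, self.edge_sets)


def _ceil_div(length: float, h: float) -> int:
    return max(1, math.ceil(length / h - 1e-9))


def _face_nodes(face: np.ndarray, n: int) -> np.ndarray:
    """n+1 evenly spaced points along a 2-point face, endpoints included."""
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return face[0][None, :] * (1 - t) + face[1][None, :] * t


def generate_mesh(geom: PlexusGeometry, h_max: float = 2.0,
                  h_min: float = 0.2) -> Mesh:
    """Mesh the plexus domain with mapped quads at global size bounds.

    The cross-section of each root gets ``max(2, ...)`` divisions sized by
    its longest face; root/trunk axial divisions honour ``h_max``.  All
    interfaces are conforming (see module docstring).  Raises
    :class:`MeshError` on degenerate elements.
    """
    params = MeshParams(h_max, h_min)
    b = _Builder()

    # cross divisions and shared face node arrays per root
    n_w: dict[str, int] = {}
    prox_nodes: dict[str, np.ndarray] = {}
    dist_nodes: dict[str, np.ndarray] = {}
    for rid in ROOT_IDS:
        strip = geom.roots[rid]
        lp = np.linalg.norm(strip.prox_face[0] - strip.prox_face[1])
        ld = np.linalg.norm(strip.dist_face[0] - strip.dist_face[1])
        n = max(2, _ceil_div(max(lp, ld, strip.width), params.h_max))
        n_w[rid] = n
        prox_nodes[rid] = _face_nodes(strip.prox_face, n)
        dist_nodes[rid] = _face_nodes(strip.dist_face, n)

    # ---- cord: tensor grid whose y-spacing embeds the junction faces ----
    cord = geom.cord
    nx = _ceil_div(cord.cord_width, params.h_max)
    if nx % 2:
        nx += 1  # keep a node column on the cord midline
    xs = np.linspace(0.0, cord.cord_width, nx + 1)

    ys_desc: list[float] = []

    def _extend(yvals):
        for y in yvals:
            if not ys_desc or y < ys_desc[-1] - 1e-9:
                ys_desc.append(float(y))

    cursor = cord.cord_length
    _extend([cursor])
    for rid in ROOT_IDS:
        face_y = prox_nodes[rid][:, 1]  # descending (cranial -> caudal)
        gap = cursor - face_y[0]
        if gap > 1e-9:
            nfill = _ceil_div(gap, params.h_max)
            _extend(np.linspace(cursor, face_y[0], nfill + 1)[1:])
        _extend(face_y)
        cursor = face_y[-1]
    if cursor > 1e-9:
        nfill = _ceil_div(cursor, params.h_max)
        _extend(np.linspace(cursor, 0.0, nfill + 1)[1:])

    ys = np.asarray(ys_desc)
    cord_pts = np.empty((len(ys), len(xs), 2))
    cord_pts[:, :, 0] = xs[None, :]
    cord_pts[:, :, 1] = ys[:, None]
    cord_ids = b.grid(cord_pts)
    b.quads_from_grid(cord_ids, "cord")
    b.chain_edges("cord_midline", cord_ids[:, nx // 2])

    # ---- roots: one mapped patch each, proximal face shared with cord ----
    for rid in ROOT_IDS:
        strip = geom.roots[rid]
        pn, dn = prox_nodes[rid], dist_nodes[rid]
        axial = np.linalg.norm(0.5 * (dn[0] + dn[-1]) - 0.5 * (pn[0] + pn[-1]))
        n_ax = _ceil_div(axial, params.h_max)
        t = np.linspace(0.0, 1.0, n_ax + 1)[:, None, None]
        pts = pn[None, :, :] * (1 - t) + dn[None, :, :] * t
        ids = b.grid(pts)
        b.quads_from_grid(ids, f"root:{rid}")
        b.chain_edges(f"junction_{rid}", ids[0, :])
        if rid == "C5":
            b.chain_edges("superior_edge", ids[:, 0])
        if rid == "T1":
            b.chain_edges("inferior_edge", ids[:, -1])

    # ---- trunks: cross-section = concatenated member distal faces ----
    for tid in TRUNK_IDS:
        trunk = geom.trunks[tid]
        members = TRUNK_MEMBERS[tid]
        cross = dist_nodes[members[0]]
        for m in members[1:]:
            cross = np.vstack([cross, dist_nodes[m][1:]])  # shared node at X
        n_ax = _ceil_div(trunk.length, params.h_max)
        t = np.linspace(0.0, 1.0, n_ax + 1)[:, None, None]
        offs = (trunk.length * trunk.direction)[None, None, :]
        pts = cross[None, :, :] + t * offs
        ids = b.grid(pts)
        b.quads_from_grid(ids, f"trunk:{tid}")
        b.chain_edges(f"distal_{tid}", ids[-1, :])

    mesh = b.build()
    _check_no_near_duplicates(mesh)
    return mesh


def rect_mesh(length: float, width: float, h: float | None = None,
              nx: int | None = None, ny: int | None = None) -> Mesh:
    """Structured quad mesh of an axis-aligned rectangle [0,L]x[0,W].

    Used by the analytic verification fixtures.  Edge sets: ``left``,
    ``right``, ``bottom``, ``top``.
    """
    if nx is None or ny is None:
        if h is None:
            raise ValueError("give either h or both nx and ny")
        nx, ny = _ceil_div(length, h), _ceil_div(width, h)
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, width, ny + 1)
    b = _Builder()
    pts = np.empty((nx + 1, ny + 1, 2))
    pts[:, :, 0] = xs[:, None]
    pts[:, :, 1] = ys[None, :]
    ids = b.grid(pts)
    b.quads_from_grid(ids, "rect")
    b.chain_edges("left", ids[0, :])
    b.chain_edges("right", ids[-1, :])
    b.chain_edges("bottom", ids[:, 0])
    b.chain_edges("top", ids[:, -1])
    return b.build()


def _check_no_near_duplicates(mesh: Mesh, tol: float = 1e-9):
    key = np.round(mesh.nodes / max(tol, 1e-12)).astype(np.int64)
    _, counts = np.unique(key, axis=0, return_counts=True)
    if (counts > 1).any():
        raise MeshError("mesh contains distinct nodes closer than the "
                        "duplicate tolerance")


def check_mesh_quality(mesh: Mesh, params: MeshParams,
                       tol: float = 0.3) -> dict[str, float]:
    """Quality report: min Jacobian, edge-length range vs the size bounds."""
    min_jac = math.inf
    for conn in mesh.quads:
        min_jac = min(min_jac, quad_jacobians(mesh.nodes[conn]).min())
    for conn in mesh.tris:
        min_jac = min(min_jac, 2.0 * tri_area(mesh.nodes[conn]))
    el = mesh.edge_lengths()
    return {
        "min_jacobian": float(min_jac),
        "min_edge": float(el.min()),
        "max_edge": float(el.max()),
        "edge_low_bound": params.h_min * (1 - tol),
        "edge_high_bound": params.h_max * (1 + tol),
        "within_bounds": bool(el.min() >= params.h_min * (1 - tol) - 1e-12
                              and el.max() <= params.h_max * (1 + tol) + 1e-12),
        "quad_fraction": mesh.quad_fraction(),
    }


# ---------------------------------------------------------------------------
# exports


def to_abaqus_inp(mesh: Mesh) -> str:
    """Mesh as an Abaqus INP deck (nodes, CPS4/CPS3 cards, element sets,
    edge sets exported as node sets)."""
    lines = ["*HEADING", "plexusfem mesh export", "*NODE"]
    for i, (x, y) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.9g}, {y:.9g}")
    eid = 1
    regions: dict[str, list[int]] = {}
    if len(mesh.quads):
        lines.append("*ELEMENT, TYPE=CPS4")
        for conn, tag in zip(mesh.quads, mesh.quad_tags):
            lines.append(f"{eid}, " + ", ".join(str(int(n) + 1) for n in conn))
            regions.setdefault(tag, []).append(eid)
            eid += 1
    if len(mesh.tris):
        lines.append("*ELEMENT, TYPE=CPS3")
        for conn, tag in zip(mesh.tris, mesh.tri_tags):
            lines.append(f"{eid}, " + ", ".join(str(int(n) + 1) for n in conn))
            regions.setdefault(tag, []).append(eid)
            eid += 1
    for tag, ids in regions.items():
        name = tag.replace(":", "_").upper()
        lines.append(f"*ELSET, ELSET={name}")
        for k in range(0, len(ids), 16):
            lines.append(", ".join(str(i) for i in ids[k:k + 16]))
    for name, _ in mesh.edge_sets.items():
        nids = mesh.edge_set_nodes(name) + 1
        lines.append(f"*NSET, NSET={name.upper()}")
        for k in range(0, len(nids), 16):
            lines.append(", ".join(str(int(i)) for i in nids[k:k + 16]))
    return "\n".join(lines) + "\n"


def to_vtk(mesh: Mesh, point_data: dict[str, np.ndarray] | None = None,
           cell_data: dict[str, np.ndarray] | None = None) -> str:
    """Mesh (and optional fields) as a legacy ASCII VTK unstructured grid."""
    n = mesh.n_nodes
    lines = ["# vtk DataFile Version 3.0", "plexusfem export", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {n} double"]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9g} {y:.9g} 0")
    cells = [list(map(int, c)) for c in mesh.quads] + \
            [list(map(int, c)) for c in mesh.tris]
    total = sum(len(c) + 1 for c in cells)
    lines.append(f"CELLS {len(cells)} {total}")
    for c in cells:
        lines.append(str(len(c)) + " " + " ".join(map(str, c)))
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += ["9"] * len(mesh.quads) + ["5"] * len(mesh.tris)
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                lines.append(f"VECTORS {name} double")
                for row in arr:
                    lines.append(f"{row[0]:.9g} {row[1]:.9g} 0")
            else:
                lines.append(f"SCALARS {name} double 1\nLOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in arr]
    if cell_data:
        lines.append(f"CELL_DATA {len(cells)}")
        for name, arr in cell_data.items():
            lines.append(f"SCALARS {name} double 1\nLOOKUP_TABLE default")
            lines += [f"{v:.9g}" for v in np.asarray(arr)]
    return "\n".join(lines) + "\n"
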