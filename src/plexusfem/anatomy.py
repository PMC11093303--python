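"""Parametric 2D geometry of the neonatal brachial plexus.

The model plane contains the spinal cord (a vertical strip, cranial = +y)
and the five spinal nerve roots C5-T1 that leave its lateral surface,
converge pairwise (C5+C6, C8+T1) or continue singly (C7), and form the
upper, middle and lower trunks.  Every structure is a constant-width
strip; widths are the clinically measured cranial-caudal root diameters,
which lie in the plane of analysis.

Construction of a two-root trunk
--------------------------------
The two member roots leave the cord at configurable angles and converge.
Their *inner* lateral edges intersect at a point ``X``; the trunk's
proximal face is the straight segment through ``X`` perpendicular to the
bisector of the two root directions, truncated by the roots' *outer*
lateral edges.  The member strips therefore tile the trunk face exactly
(C5 above ``X``, C6 below it, and likewise C8/T1), which later yields a
conforming quadrilateral mesh across the merge with no gap or overlap.

Root centreline *paths* carry the anatomical lengths (sums of the
measured spinal-to-DRG, DRG-to-foramen and foramen-to-trunk segments)
independently of where the mitred strip ends; reported trunk path
lengths are root path + trunk length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .errors import GeometryInfeasibleError

ROOT_IDS = ("C5", "C6", "C7", "C8", "T1")
TRUNK_IDS = ("upper", "middle", "lower")
TRUNK_MEMBERS = {"upper": ("C5", "C6"), "middle": ("C7",), "lower": ("C8", "T1")}
#: Representative root whose centreline, continued by the trunk, defines
#: the reported cord-to-distal-trunk path (C5 for upper, C8 for lower).
TRUNK_REPRESENTATIVE = {"upper": "C5", "middle": "C7", "lower": "C8"}

_OVERLAP_TOL = 1e-6  # mm^2, allowed spurious intersection area between strips


def _rot90(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by +90 degrees (counter-clockwise)."""
    return np.array([-v[1], v[0]])


def _intersect_lines(p1, u1, p2, u2):
    """Intersection of lines p1+s*u1 and p2+r*u2; returns (point, s, r)."""
    a = np.column_stack([u1, -u2])
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    if abs(det) < 1e-12:
        return None
    s, r = np.linalg.solve(a, np.asarray(p2) - np.asarray(p1))
    return np.asarray(p1) + s * np.asarray(u1), float(s), float(r)


@dataclass(frozen=True)
class RootDimensions:
    """Measured cross-section diameters and segment lengths of one root (mm).

    ``len_drg_to_foramen`` is ``None`` for T1, whose dorsal root ganglion
    sits at the foramen in the source measurements.
    """

    root_id: str
    d_cranial_caudal: float
    d_transverse: float
    len_spinal_to_drg: float
    len_drg_to_foramen: float | None
    len_foramen_to_trunk: float

    def __post_init__(self):
        if self.root_id not in ROOT_IDS:
            raise ValueError(f"unknown root id {self.root_id!r}")
        vals = [self.d_cranial_caudal, self.d_transverse,
                self.len_spinal_to_drg, self.len_foramen_to_trunk]
        if self.len_drg_to_foramen is not None:
            vals.append(self.len_drg_to_foramen)
        if any(v <= 0 for v in vals):
            raise ValueError(f"{self.root_id}: all dimensions must be positive")

    @property
    def segment_lengths(self) -> tuple[float, ...]:
        if self.len_drg_to_foramen is None:
            return (self.len_spinal_to_drg, self.len_foramen_to_trunk)
        return (self.len_spinal_to_drg, self.len_drg_to_foramen,
                self.len_foramen_to_trunk)

    @property
    def total_length(self) -> float:
        """Cord-surface-to-trunk length of the root centreline (mm)."""
        return float(sum(self.segment_lengths))


#: Average infant dimensions (mm) measured intra-operatively; the bundled
#: baseline anatomy.  Cranial-caudal diameters are the in-plane strip widths.
DEFAULT_ROOT_DIMENSIONS: dict[str, RootDimensions] = {
    "C5": RootDimensions("C5", 3.0, 1.1, 7.5, 9.0, 14.0),
    "C6": RootDimensions("C6", 3.1, 1.3, 7.5, 8.0, 15.5),
    "C7": RootDimensions("C7", 3.8, 1.6, 7.5, 7.0, 19.0),
    "C8": RootDimensions("C8", 2.7, 1.4, 7.5, 5.5, 7.0),
    "T1": RootDimensions("T1", 2.5, 1.4, 7.5, None, 6.0),
}


@dataclass(frozen=True)
class CordParameters:
    """Spinal-cord strip dimensions and root attachment levels.

    ``root_attachment_positions`` are axial coordinates (mm) measured
    caudally from the cranial end of the cord strip, one per root in
    C5..T1 order, strictly increasing.
    """

    cord_width: float
    cord_length: float
    root_attachment_positions: tuple[float, ...]

    def __post_init__(self):
        pos = tuple(float(p) for p in self.root_attachment_positions)
        object.__setattr__(self, "root_attachment_positions", pos)
        if len(pos) != len(ROOT_IDS):
            raise ValueError("need one attachment position per root (5)")
        if self.cord_width <= 0 or self.cord_length <= 0:
            raise ValueError("cord dimensions must be positive")
        if any(p <= 0 for p in pos):
            raise ValueError("attachment positions must be positive")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("attachment positions must increase from C5 to T1")
        if self.cord_length <= max(pos):
            raise ValueError("cord_length must exceed the caudal-most attachment")

    def attachment_y(self, root_id: str) -> float:
        """World y-coordinate (cranial = +y) of the root attachment point."""
        return self.cord_length - self.root_attachment_positions[ROOT_IDS.index(root_id)]


@dataclass(frozen=True)
class RootStrip:
    """Drawn geometry of one root: a straight strip of width d_cranial_caudal."""

    root_id: str
    angle_deg: float          # between centreline and the caudal cord axis
    width: float              # mm, cranial-caudal diameter
    attach: np.ndarray        # centreline origin on the cord surface
    direction: np.ndarray     # unit centreline direction
    normal: np.ndarray        # unit in-plane normal (cranial side)
    path: np.ndarray          # (2, 2) centreline polyline, cord -> anatomical end
    prox_face: np.ndarray     # (2, 2) [cranial, caudal] endpoints on cord surface
    dist_face: np.ndarray     # (2, 2) [cranial, caudal] endpoints on trunk face

    @property
    def length(self) -> float:
        """Anatomical centreline length (mm)."""
        return float(np.linalg.norm(self.path[1] - self.path[0]))

    @property
    def corners(self) -> np.ndarray:
        """Strip corners (prox-cranial, dist-cranial, dist-caudal, prox-caudal)."""
        return np.array([self.prox_face[0], self.dist_face[0],
                         self.dist_face[1], self.prox_face[1]])

    def polygon(self) -> Polygon:
        return Polygon(self.corners)


@dataclass(frozen=True)
class TrunkStrip:
    """Drawn geometry of one trunk strip distal to its proximal (merge) face."""

    trunk_id: str
    members: tuple[str, ...]
    direction: np.ndarray       # unit axis, proximal -> distal
    length: float               # mm, along the axis
    prox_face: np.ndarray       # (2, 2) [cranial, caudal] endpoints
    split_point: np.ndarray | None  # merge point X on the face (2-root trunks)
    path: np.ndarray            # (2, 2) centreline, face midpoint -> distal end

    @property
    def width(self) -> float:
        """Drawn face width (mm); tiles the member-root mitred faces exactly."""
        return float(np.linalg.norm(self.prox_face[0] - self.prox_face[1]))

    @property
    def dist_face(self) -> np.ndarray:
        return self.prox_face + self.length * self.direction

    @property
    def corners(self) -> np.ndarray:
        d = self.dist_face
        return np.array([self.prox_face[0], d[0], d[1], self.prox_face[1]])

    def polygon(self) -> Polygon:
        return Polygon(self.corners)


@dataclass(frozen=True)
class PlexusGeometry:
    """Complete planar plexus domain plus the inputs it was built from."""

    dims: dict[str, RootDimensions]
    cord: CordParameters
    root_angles: dict[str, float]
    trunk_lengths: dict[str, float]
    roots: dict[str, RootStrip]
    trunks: dict[str, TrunkStrip]
    #: configured trunk axis angles (None = bisector of member directions)
    trunk_angles: dict[str, float | None] = field(
        default_factory=lambda: {t: None for t in TRUNK_IDS})

    @property
    def cord_polygon(self) -> Polygon:
        c = self.cord
        return Polygon([(0, 0), (c.cord_width, 0),
                        (c.cord_width, c.cord_length), (0, c.cord_length)])

    def region_polygons(self) -> dict[str, Polygon]:
        out = {"cord": self.cord_polygon}
        for rid, strip in self.roots.items():
            out[f"root:{rid}"] = strip.polygon()
        for tid, trunk in self.trunks.items():
            out[f"trunk:{tid}"] = trunk.polygon()
        return out

    def domain(self) -> Polygon:
        return unary_union(list(self.region_polygons().values()))

    def to_wkt(self) -> str:
        """All region outlines as a WKT GEOMETRYCOLLECTION."""
        from shapely.geometry import GeometryCollection
        return GeometryCollection(list(self.region_polygons().values())).wkt

    def to_svg(self) -> str:
        """Plottable outline of the plexus domain (standalone SVG document)."""
        polys = self.region_polygons()
        xs, ys = [], []
        for p in polys.values():
            bx = p.bounds
            xs += [bx[0], bx[2]]
            ys += [bx[1], bx[3]]
        pad = 2.0
        x0, x1 = min(xs) - pad, max(xs) + pad
        y0, y1 = min(ys) - pad, max(ys) + pad
        parts = [f'<svg xmlns="http://www.w3.org/2000/svg" '
                 f'viewBox="{x0:.2f} {-y1:.2f} {x1 - x0:.2f} {y1 - y0:.2f}">']
        for name, p in polys.items():
            pts = " ".join(f"{x:.4f},{-y:.4f}" for x, y in p.exterior.coords)
            parts.append(f'<polygon points="{pts}" fill="none" '
                         f'stroke="black" stroke-width="0.15"><title>{name}</title>'
                         f'</polygon>')
        parts.append("</svg>")
        return "\n".join(parts)


def _root_direction(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit centreline direction and cranial-side normal for a root angle.

    The angle is measured between the root centreline and the caudal cord
    direction (-y): 90 deg is perpendicular to the cord, <90 deg descends.
    """
    th = math.radians(angle_deg)
    u = np.array([math.sin(th), -math.cos(th)])
    return u, _rot90(u)


def _prox_face(attach: np.ndarray, width: float, angle_deg: float) -> np.ndarray:
    """Vertical mitre cut of the strip on the cord surface, [cranial, caudal]."""
    half = width / (2.0 * math.sin(math.radians(angle_deg)))
    return np.array([attach + [0.0, half], attach - [0.0, half]])


def _build_two_root_trunk(trunk_id, strip_a, strip_b, trunk_length,
                          trunk_angle=None):
    """Merge a cranial/caudal root pair into a trunk (see module docstring).

    ``trunk_angle`` (degrees, same convention as root angles) overrides
    the default bisector direction of the trunk axis; the proximal face
    stays perpendicular to the trunk axis and passes through the inner-
    edge intersection X, so an oblique trunk loads its member roots
    partly in bending.
    """
    inner_a = strip_a.attach - 0.5 * strip_a.width * strip_a.normal
    inner_b = strip_b.attach + 0.5 * strip_b.width * strip_b.normal
    hit = _intersect_lines(inner_a, strip_a.direction, inner_b, strip_b.direction)
    if hit is None:
        raise GeometryInfeasibleError(
            f"roots {strip_a.root_id} and {strip_b.root_id} are parallel and "
            f"cannot merge into the {trunk_id} trunk")
    x_pt, s_a, s_b = hit
    if s_a <= 0 or s_b <= 0:
        raise GeometryInfeasibleError(
            f"roots {strip_a.root_id} and {strip_b.root_id} diverge "
            f"(inner edges meet behind the cord); {trunk_id} trunk infeasible")
    if trunk_angle is None:
        t = strip_a.direction + strip_b.direction
        t = t / np.linalg.norm(t)
    else:
        t, _ = _root_direction(float(trunk_angle))
    n_t = _rot90(t)
    outer_a = strip_a.attach + 0.5 * strip_a.width * strip_a.normal
    outer_b = strip_b.attach - 0.5 * strip_b.width * strip_b.normal
    hit_a = _intersect_lines(outer_a, strip_a.direction, x_pt, n_t)
    hit_b = _intersect_lines(outer_b, strip_b.direction, x_pt, n_t)
    if hit_a is None or hit_b is None:
        raise GeometryInfeasibleError(
            f"{trunk_id} trunk face construction failed for "
            f"{strip_a.root_id}/{strip_b.root_id}")
    e_a, s_out_a, _ = hit_a
    e_b, s_out_b, _ = hit_b
    if s_out_a <= 0 or s_out_b <= 0:
        raise GeometryInfeasibleError(
            f"{trunk_id} trunk face cuts roots {strip_a.root_id}/"
            f"{strip_b.root_id} behind the cord surface")
    if (e_a - x_pt) @ n_t <= 0 or (e_b - x_pt) @ n_t >= 0:
        raise GeometryInfeasibleError(
            f"{trunk_id} trunk face orientation degenerate for "
            f"{strip_a.root_id}/{strip_b.root_id}")
    face = np.array([e_a, e_b])
    mid = 0.5 * (e_a + e_b)
    trunk = TrunkStrip(trunk_id, (strip_a.root_id, strip_b.root_id), t,
                       float(trunk_length), face, x_pt,
                       np.array([mid, mid + trunk_length * t]))
    strip_a = replace(strip_a, dist_face=np.array([e_a, x_pt]))
    strip_b = replace(strip_b, dist_face=np.array([x_pt, e_b]))
    return trunk, strip_a, strip_b


def _build_single_root_trunk(trunk_id, strip, trunk_length, trunk_angle=None):
    end = strip.path[1]
    if trunk_angle is None:
        t = strip.direction
    else:
        t, _ = _root_direction(float(trunk_angle))
    n_t = _rot90(t)
    # face through the anatomical root end, perpendicular to the trunk axis
    hit_top = _intersect_lines(strip.attach + 0.5 * strip.width * strip.normal,
                               strip.direction, end, n_t)
    hit_bot = _intersect_lines(strip.attach - 0.5 * strip.width * strip.normal,
                               strip.direction, end, n_t)
    if hit_top is None or hit_bot is None:
        raise GeometryInfeasibleError(
            f"{trunk_id} trunk axis parallel to root {strip.root_id} edges")
    e_top, s_top, _ = hit_top
    e_bot, s_bot, _ = hit_bot
    if s_top <= 0 or s_bot <= 0:
        raise GeometryInfeasibleError(
            f"{trunk_id} trunk face cuts root {strip.root_id} behind the cord")
    face = np.array([e_top, e_bot])
    trunk = TrunkStrip(trunk_id, (strip.root_id,), t, float(trunk_length),
                       face, None, np.array([end, end + trunk_length * t]))
    strip = replace(strip, dist_face=face.copy())
    return trunk, strip


def _check_cord_faces(strips: dict[str, RootStrip], cord: CordParameters):
    faces = [(rid, strips[rid].prox_face) for rid in ROOT_IDS]
    for rid, face in faces:
        if face[0][1] >= cord.cord_length or face[1][1] <= 0:
            raise GeometryInfeasibleError(
                f"root {rid} junction face extends beyond the cord strip")
    for (ra, fa), (rb, fb) in zip(faces, faces[1:]):
        # fa is the more cranial face; its caudal end must clear fb's cranial end
        if fa[1][1] <= fb[0][1]:
            raise GeometryInfeasibleError(
                f"root strips {ra} and {rb} overlap on the cord surface "
                f"(angles too convergent for the attachment spacing)")


def _check_strip_overlaps(strips, trunks):
    shapes = [(f"root {rid}", strips[rid].polygon()) for rid in ROOT_IDS]
    shapes += [(f"trunk {tid}", trunks[tid].polygon()) for tid in TRUNK_IDS]
    for i, (na, pa) in enumerate(shapes):
        if not pa.is_valid:
            raise GeometryInfeasibleError(f"{na} strip is self-intersecting")
        for nb, pb in shapes[i + 1:]:
            if pa.intersection(pb).area > _OVERLAP_TOL:
                # members legitimately share a boundary with their trunk,
                # but positive overlap area is always an error
                raise GeometryInfeasibleError(
                    f"{na} and {nb} overlap; geometry infeasible")


def build_baseline_geometry(
    dims: dict[str, RootDimensions],
    cord: CordParameters,
    angles: dict[str, float],
    trunk_lengths: dict[str, float],
    trunk_angles: dict[str, float | None] | None = None,
) -> PlexusGeometry:
    """Build the full plexus domain from dimensions, angles and trunk lengths.

    ``trunk_angles`` optionally fixes each trunk's axis direction (same
    angle convention as the roots); by default a trunk runs along the
    bisector of its member-root directions.  A fixed trunk axis oblique
    to the member roots loads them partly in bending, which is what
    makes the junction stresses sensitive to root-angle variations.

    Raises :class:`GeometryInfeasibleError` (naming the offending pair)
    when root strips overlap on the cord or a trunk merge is impossible.
    """
    if set(dims) != set(ROOT_IDS) or set(angles) != set(ROOT_IDS):
        raise ValueError("dims and angles must cover exactly C5..T1")
    if set(trunk_lengths) != set(TRUNK_IDS):
        raise ValueError("trunk_lengths must cover upper/middle/lower")
    for rid, a in angles.items():
        if not 0.0 < a < 180.0:
            raise ValueError(f"root angle {rid}={a} outside (0, 180) degrees")
    for tid, L in trunk_lengths.items():
        if L <= 0:
            raise ValueError(f"trunk length {tid}={L} must be positive")

    strips: dict[str, RootStrip] = {}
    for rid in ROOT_IDS:
        d = dims[rid]
        a = float(angles[rid])
        u, n = _root_direction(a)
        attach = np.array([cord.cord_width, cord.attachment_y(rid)])
        path = np.array([attach, attach + d.total_length * u])
        strips[rid] = RootStrip(rid, a, d.d_cranial_caudal, attach, u, n,
                                path, _prox_face(attach, d.d_cranial_caudal, a),
                                dist_face=np.empty((2, 2)))
    _check_cord_faces(strips, cord)

    t_ang = {t: None for t in TRUNK_IDS}
    if trunk_angles:
        t_ang.update(trunk_angles)
    trunks: dict[str, TrunkStrip] = {}
    trunks["upper"], strips["C5"], strips["C6"] = _build_two_root_trunk(
        "upper", strips["C5"], strips["C6"], trunk_lengths["upper"],
        t_ang["upper"])
    trunks["middle"], strips["C7"] = _build_single_root_trunk(
        "middle", strips["C7"], trunk_lengths["middle"], t_ang["middle"])
    trunks["lower"], strips["C8"], strips["T1"] = _build_two_root_trunk(
        "lower", strips["C8"], strips["T1"], trunk_lengths["lower"],
        t_ang["lower"])

    for tid in TRUNK_IDS:
        face = trunks[tid].prox_face
        if min(face[0][0], face[1][0]) <= cord.cord_width:
            raise GeometryInfeasibleError(
                f"{tid} trunk face reaches back into the cord strip")
    _check_strip_overlaps(strips, trunks)

    geom = PlexusGeometry(dict(dims), cord, {r: float(angles[r]) for r in ROOT_IDS},
                          {t: float(trunk_lengths[t]) for t in TRUNK_IDS},
                          strips, trunks, t_ang)
    # connectivity check with a tiny buffer so exact shared faces/points
    # are not split by floating-point noding
    dom = unary_union([p.buffer(1e-6) for p in geom.region_polygons().values()])
    if dom.geom_type != "Polygon":
        raise GeometryInfeasibleError(
            "plexus regions do not form a single connected domain")
    return geom


def perturb_root_angles(geom: PlexusGeometry, delta: float,
                        max_delta: float = 10.0,
                        roots: tuple[str, ...] | None = None) -> PlexusGeometry:
    """Rotate root centrelines about their cord junctions by ``delta`` degrees.

    All five roots are perturbed simultaneously by default (``roots``
    restricts the change to a subset).  Segment lengths are preserved
    exactly; trunks are rebuilt on the displaced root ends.
    """
    if abs(delta) > max_delta:
        raise ValueError(f"|delta|={abs(delta)} exceeds safe range {max_delta} deg")
    sel = ROOT_IDS if roots is None else tuple(roots)
    angles = {rid: geom.root_angles[rid] + (delta if rid in sel else 0.0)
              for rid in ROOT_IDS}
    # trunk axes stay fixed: only the root-cord angles vary
    return build_baseline_geometry(geom.dims, geom.cord, angles,
                                   geom.trunk_lengths, geom.trunk_angles)


def path_length(geom: PlexusGeometry, trunk: str) -> float:
    """Arc length (mm) of the representative centreline from the cord
    surface to the distal trunk face: root path plus trunk length."""
    if trunk not in TRUNK_IDS:
        raise ValueError(f"unknown trunk {trunk!r}")
    rep = TRUNK_REPRESENTATIVE[trunk]
    root_len = float(np.linalg.norm(geom.roots[rep].path[1] - geom.roots[rep].path[0]))
    t = geom.trunks[trunk]
    return root_len + float(np.linalg.norm(t.path[1] - t.path[0]))
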