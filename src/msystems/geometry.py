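"""Euclidean 3-D primitives for M-system simulations.

Length unit convention: 1 unit = one tile edge length. Tiles are rigid
1-D (rods) or 2-D (planar polygons) obstructive objects; floating objects
are points. This module supplies poses (rigid transforms), tile shapes,
connector geometry, obstruction (minimum-distance) tests, the uniform
Brownian displacement applied each iteration, and point-in-polyhedron
tests used for compartment membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Pose",
    "TileShape",
    "Connector",
    "to_world",
    "overlap",
    "brownian_step",
    "point_in_polyhedron",
    "DEFAULT_CLEARANCE",
]

#: Default clearance for obstruction tests, in tile-edge units.
DEFAULT_CLEARANCE = 0.01

_TOL = 1e-9


def _as_vec3(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("vector components must be finite")
    return a


@dataclass(frozen=True)
class Pose:
    """Rigid placement: a position and a unit quaternion (x, y, z, w)."""

    position: np.ndarray
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0])
    )

    def __post_init__(self):
        object.__setattr__(self, "position", _as_vec3(self.position))
        q = np.asarray(self.orientation, dtype=float)
        if q.shape != (4,):
            raise ValueError("orientation must be a quaternion (x, y, z, w)")
        n = float(np.linalg.norm(q))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"orientation quaternion norm {n} is not 1 within 1e-9")
        object.__setattr__(self, "orientation", q)

    @staticmethod
    def identity() -> "Pose":
        return Pose(np.zeros(3))

    @staticmethod
    def from_rotation(rot: Rotation, position=(0.0, 0.0, 0.0)) -> "Pose":
        q = rot.as_quat()
        q = q / np.linalg.norm(q)
        return Pose(_as_vec3(position), q)

    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.orientation)


def to_world(pose: Pose, p) -> np.ndarray:
    """Map a point from the tile's local frame to world coordinates.

    A rigid transform: rotation by the pose quaternion followed by
    translation. Preserves pairwise distances.
    """
    return pose.rotation().apply(_as_vec3(p)) + pose.position


@dataclass(frozen=True)
class TileShape:
    """A rigid tile shape in its local frame.

    kind "polygon2D": >= 3 coplanar vertices forming a simple polygon;
    by convention the polygon normal is +z and the first vertex lies on
    the +x axis. kind "rod1D": exactly two vertices, positive length.
    """

    kind: str
    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        if self.kind == "rod1D":
            if v.shape[0] != 2:
                raise ValueError("rod1D requires exactly 2 vertices")
            if np.linalg.norm(v[1] - v[0]) <= 0:
                raise ValueError("rod length must be > 0")
        elif self.kind == "polygon2D":
            if v.shape[0] < 3:
                raise ValueError("polygon2D requires >= 3 vertices")
            # coplanarity within 1e-9 against the best-fit plane
            c = v.mean(axis=0)
            _, s, _ = np.linalg.svd(v - c)
            if s[-1] > 1e-9 * max(1.0, s[0]):
                raise ValueError("polygon2D vertices are not coplanar within 1e-9")
        else:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        object.__setattr__(self, "vertices", v)

    @staticmethod
    def regular_polygon(n_sides: int, edge: float = 1.0) -> "TileShape":
        """Regular n-gon of given edge length in the z=0 plane.

        Circumradius R = edge / (2 sin(pi/n)); first vertex on the +x axis.
        """
        r = edge / (2.0 * np.sin(np.pi / n_sides))
        ang = 2.0 * np.pi * np.arange(n_sides) / n_sides
        return TileShape(
            "polygon2D",
            np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n_sides)]),
        )

    @staticmethod
    def rectangle(width: float, height: float) -> "TileShape":
        w, h = width / 2.0, height / 2.0
        return TileShape(
            "polygon2D",
            np.array([[w, -h, 0.0], [w, h, 0.0], [-w, h, 0.0], [-w, -h, 0.0]]),
        )

    @staticmethod
    def rod(length: float) -> "TileShape":
        return TileShape("rod1D", np.array([[0.0, 0.0, 0.0], [length, 0.0, 0.0]]))

    def placed(self, pose: Pose) -> np.ndarray:
        """World-frame vertices under the given pose."""
        return pose.rotation().apply(self.vertices) + pose.position


@dataclass(frozen=True)
class Connector:
    """A glued bonding site on a tile boundary.

    site: a point (3,) or segment (2, 3) in the tile local frame, lying on
    the tile boundary. glue: glue label. attach_angle: dihedral angle in
    radians at which an incoming tile is oriented relative to the host
    tile plane (0 <= angle < 2 pi).
    """

    site: np.ndarray
    glue: str
    attach_angle: float = 0.0

    def __post_init__(self):
        s = np.asarray(self.site, dtype=float)
        if s.shape not in ((3,), (2, 3)):
            raise ValueError("connector site must be a point (3,) or segment (2,3)")
        if not (0.0 <= self.attach_angle < 2.0 * np.pi):
            raise ValueError("attach_angle must lie in [0, 2*pi)")
        object.__setattr__(self, "site", s)

    def midpoint(self) -> np.ndarray:
        return self.site if self.site.ndim == 1 else self.site.mean(axis=0)


# ---------------------------------------------------------------------------
# minimum distance between placed shapes (obstruction tests)
# ---------------------------------------------------------------------------


def _seg_seg_dist(p1, q1, p2, q2) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2]."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    if a <= _TOL and e <= _TOL:
        return float(np.linalg.norm(r))
    if a <= _TOL:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= _TOL:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > _TOL else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


def _point_tri_dist(p, a, b, c) -> float:
    """Minimum distance from point p to triangle abc."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(ap))
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(bp))
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3) if d1 != d3 else 0.0
        return float(np.linalg.norm(p - (a + v * ab)))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(cp))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6) if d2 != d6 else 0.0
        return float(np.linalg.norm(p - (a + w * ac)))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(np.linalg.norm(p - (b + w * (c - b))))
    denom = 1.0 / (va + vb + vc)
    v, w = vb * denom, vc * denom
    return float(np.linalg.norm(p - (a + ab * v + ac * w)))


def _seg_tri_intersects(p, q, a, b, c) -> bool:
    """True if segment [p, q] crosses the interior of triangle abc."""
    n = np.cross(b - a, c - a)
    dp, dq = n @ (p - a), n @ (q - a)
    if dp * dq > 0 or (abs(dp) < _TOL and abs(dq) < _TOL):
        return False  # same side, or coplanar (edge distances handle that)
    denom = dp - dq
    if abs(denom) < _TOL:
        return False
    t = dp / denom
    x = p + t * (q - p)
    # barycentric containment
    v0, v1, v2 = c - a, b - a, x - a
    d00, d01, d02 = v0 @ v0, v0 @ v1, v0 @ v2
    d11, d12 = v1 @ v1, v1 @ v2
    den = d00 * d11 - d01 * d01
    if abs(den) < _TOL:
        return False
    u = (d11 * d02 - d01 * d12) / den
    v = (d00 * d12 - d01 * d02) / den
    return u >= -1e-12 and v >= -1e-12 and u + v <= 1 + 1e-12


def _tri_tri_dist(t1, t2) -> float:
    a1, b1, c1 = t1
    a2, b2, c2 = t2
    e1 = [(a1, b1), (b1, c1), (c1, a1)]
    e2 = [(a2, b2), (b2, c2), (c2, a2)]
    for p, q in e1:
        if _seg_tri_intersects(p, q, a2, b2, c2):
            return 0.0
    for p, q in e2:
        if _seg_tri_intersects(p, q, a1, b1, c1):
            return 0.0
    d = min(_seg_seg_dist(p, q, r, s) for p, q in e1 for r, s in e2)
    d = min(d, *(_point_tri_dist(v, a2, b2, c2) for v in t1))
    d = min(d, *(_point_tri_dist(v, a1, b1, c1) for v in t2))
    return d


def _triangles(verts: np.ndarray):
    """Fan triangulation of a (convex or star-shaped) polygon."""
    c = verts.mean(axis=0)
    n = len(verts)
    return [(c, verts[i], verts[(i + 1) % n]) for i in range(n)]


def shape_distance(shape_a: TileShape, pose_a: Pose, shape_b: TileShape, pose_b: Pose) -> float:
    """Minimum Euclidean distance between two placed shapes (0 if they touch)."""
    va, vb = shape_a.placed(pose_a), shape_b.placed(pose_b)
    if shape_a.kind == "rod1D" and shape_b.kind == "rod1D":
        return _seg_seg_dist(va[0], va[1], vb[0], vb[1])
    if shape_a.kind == "rod1D":
        tris = _triangles(vb)
        for t in tris:
            if _seg_tri_intersects(va[0], va[1], *t):
                return 0.0
        d = min(
            min(_seg_seg_dist(va[0], va[1], t[i], t[(i + 1) % 3]) for i in range(3))
            for t in tris
        )
        return min(d, *(min(_point_tri_dist(v, *t) for t in tris) for v in va))
    if shape_b.kind == "rod1D":
        return shape_distance(shape_b, pose_b, shape_a, pose_a)
    return min(_tri_tri_dist(t1, t2) for t1 in _triangles(va) for t2 in _triangles(vb))


def overlap(
    shape_a: TileShape,
    pose_a: Pose,
    shape_b: TileShape,
    pose_b: Pose,
    clearance: float = DEFAULT_CLEARANCE,
) -> bool:
    """True iff the minimum distance between the placed shapes is < clearance."""
    if clearance < 0:
        raise ValueError("clearance must be >= 0")
    return shape_distance(shape_a, pose_a, shape_b, pose_b) < clearance


# ---------------------------------------------------------------------------
# Brownian displacement
# ---------------------------------------------------------------------------


def brownian_step(p, step: float, rng: np.random.Generator, bounds=None) -> np.ndarray:
    """Displace a point by exactly `step` in a direction uniform on the sphere.

    If `bounds` is given as (lo, hi) arrays of an axis-aligned box, the
    result is reflected back into the box (mirror folding), conserving the
    object. The displacement norm equals `step` exactly before reflection.
    """
    p = _as_vec3(p)
    if step < 0:
        raise ValueError("step must be >= 0")
    if step == 0:
        return p.copy()
    d = rng.standard_normal(3)
    n = np.linalg.norm(d)
    while n < 1e-12:  # pragma: no cover - vanishing probability
        d = rng.standard_normal(3)
        n = np.linalg.norm(d)
    q = p + d * (step / n)
    if bounds is not None:
        q = reflect_into_box(q, bounds[0], bounds[1])
    return q


def reflect_into_box(p: np.ndarray, lo, hi) -> np.ndarray:
    """Fold a point into [lo, hi] by mirror reflection on each axis."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    span = hi - lo
    q = np.mod(p - lo, 2.0 * span)
    q = np.where(q > span, 2.0 * span - q, q)
    return lo + q


# ---------------------------------------------------------------------------
# point-in-polyhedron (ray casting)
# ---------------------------------------------------------------------------


def point_in_polyhedron(p, faces, rng: np.random.Generator | None = None) -> bool:
    """Ray-cast membership test of point p against a closed set of polygon faces.

    `faces` is a sequence of (n_i, 3) vertex arrays. Casts a ray in a
    quasi-random direction and counts crossings; retries directions that
    graze edges. Used for compartment membership (in/out side tests).
    """
    p = _as_vec3(p)
    rng = rng or np.random.default_rng(0)
    tri_faces = [t for f in faces for t in _triangles(np.asarray(f, dtype=float))]
    for _ in range(12):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        crossings = 0
        ok = True
        for a, b, c in tri_faces:
            n = np.cross(b - a, c - a)
            denom = n @ d
            if abs(denom) < 1e-12:
                continue
            t = (n @ (a - p)) / denom
            if t <= 1e-12:
                continue
            x = p + t * d
            v0, v1, v2 = c - a, b - a, x - a
            d00, d01, d02 = v0 @ v0, v0 @ v1, v0 @ v2
            d11, d12 = v1 @ v1, v1 @ v2
            den = d00 * d11 - d01 * d01
            if abs(den) < 1e-15:
                continue
            u = (d11 * d02 - d01 * d12) / den
            v = (d00 * d12 - d01 * d02) / den
            if -1e-9 < u < 1e-9 or -1e-9 < v < 1e-9 or abs(u + v - 1) < 1e-9:
                ok = False  # grazing hit: retry with a new direction
                break
            if u > 0 and v > 0 and u + v < 1:
                crossings += 1
        if ok:
            return crossings % 2 == 1
    return crossings % 2 == 1  # pragma: no cover - fallback after retries
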