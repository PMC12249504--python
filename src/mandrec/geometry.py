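"""Low-level geometric primitives shared across the planning pipeline.

All coordinates are millimetres in a patient-space RAS-like frame
(+x right, +y anterior, +z superior).  The two workhorses are
:class:`Polyline` (arc-length parameterized curves such as the mandibular
midline, fibula axis and vessel paths) and :class:`Plane` (oriented cut
planes).  Mesh cutting delegates the slicing to :mod:`trimesh` and closes
the resulting cross-sections with an ear-clipping triangulation of each
boundary loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


# --------------------------------------------------------------------------
# small vector helpers
# --------------------------------------------------------------------------

def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` normalized to unit length; raises on near-zero input."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize near-zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix (3x3) about ``axis`` by ``angle_deg`` (Rodrigues)."""
    a = unit(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(a, a)


def perpendicular_vector(axis: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``axis``.

    Prefers the projection of +z; falls back to +x when the axis is
    (anti)parallel to z.  Used as the roll-angle zero reference for fibula
    segments.
    """
    a = unit(axis)
    ref = np.array([0.0, 0.0, 1.0])
    p = ref - np.dot(ref, a) * a
    if np.linalg.norm(p) < 1e-6:
        ref = np.array([1.0, 0.0, 0.0])
        p = ref - np.dot(ref, a) * a
    return unit(p)


# --------------------------------------------------------------------------
# planes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Plane:
    """Oriented plane ``{x : normal . (x - anchor) = 0}``."""

    anchor: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor", np.asarray(self.anchor, float))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        d = (pts - self.anchor) @ self.normal
        return d[0] if np.asarray(points).ndim == 1 else d

    def project(self, point: np.ndarray) -> np.ndarray:
        """Orthogonal projection of ``point`` onto the plane."""
        p = np.asarray(point, float)
        return p - self.signed_distance(p) * self.normal

    def reflect_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        d = (np.atleast_2d(pts) - self.anchor) @ self.normal
        out = np.atleast_2d(pts) - 2.0 * d[:, None] * self.normal
        return out[0] if pts.ndim == 1 else out

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions (deterministic)."""
        u = perpendicular_vector(self.normal)
        v = unit(np.cross(self.normal, u))
        return u, v


def reflect_mesh(mesh: trimesh.Trimesh, plane: Plane) -> trimesh.Trimesh:
    """Mirror a mesh across ``plane``, flipping winding to keep it outward."""
    verts = plane.reflect_points(mesh.vertices)
    faces = mesh.faces[:, ::-1]  # reflection inverts orientation
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


# --------------------------------------------------------------------------
# polylines
# --------------------------------------------------------------------------

@dataclass
class Polyline:
    """Ordered 3D point chain with cumulative arc-length parameterization."""

    points: np.ndarray
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("polyline points must be (n, 3)")
        if len(self.points) < 2:
            raise ValueError("polyline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self._cum[-1])

    @property
    def arclengths(self) -> np.ndarray:
        return self._cum.copy()

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Point(s) at arc length ``s`` (clamped to the domain)."""
        s = np.clip(np.asarray(s, float), 0.0, self.length)
        x = np.interp(s, self._cum, self.points[:, 0])
        y = np.interp(s, self._cum, self.points[:, 1])
        z = np.interp(s, self._cum, self.points[:, 2])
        return np.stack([x, y, z], axis=-1)

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent at arc length ``s`` (central difference)."""
        h = max(self.length * 1e-4, 1e-3)
        a = self.point_at(max(0.0, s - h))
        b = self.point_at(min(self.length, s + h))
        return unit(b - a)

    def project_point(self, point: np.ndarray) -> tuple[float, np.ndarray]:
        """Closest point on the polyline: returns ``(arc_length, point)``."""
        p = np.asarray(point, float)
        a = self.points[:-1]
        b = self.points[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom < 1e-18] = 1e-18
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.einsum("ij,ij->i", proj - p, proj - p)
        i = int(np.argmin(d2))
        s = self._cum[i] + t[i] * np.linalg.norm(ab[i])
        return float(s), proj[i]

    def sub_polyline(self, s_lo: float, s_hi: float, step: float) -> "Polyline":
        """Resample the stretch ``[s_lo, s_hi]`` at spacing <= ``step``."""
        if s_hi <= s_lo:
            raise ValueError("s_hi must exceed s_lo")
        n = max(2, int(np.ceil((s_hi - s_lo) / step)) + 1)
        return Polyline(self.point_at(np.linspace(s_lo, s_hi, n)))

    def intersect_plane(self, plane: Plane) -> list[float]:
        """Arc lengths at which the polyline crosses ``plane``."""
        d = plane.signed_distance(self.points)
        out: list[float] = []
        for i in range(len(d) - 1):
            if d[i] == 0.0:
                out.append(float(self._cum[i]))
            elif d[i] * d[i + 1] < 0.0:
                t = d[i] / (d[i] - d[i + 1])
                seg = self._cum[i + 1] - self._cum[i]
                out.append(float(self._cum[i] + t * seg))
        if len(d) and d[-1] == 0.0:
            out.append(float(self._cum[-1]))
        return out

    def transformed(self, func) -> "Polyline":
        return Polyline(np.asarray(func(self.points), float))


def polyline_max_chord_deviation(points: np.ndarray) -> float:
    """Max distance of intermediate points from the end-to-end chord."""
    pts = np.asarray(points, float)
    a, b = pts[0], pts[-1]
    axis = b - a
    L = np.linalg.norm(axis)
    if L < 1e-12:
        return float(np.max(np.linalg.norm(pts - a, axis=1)))
    axis = axis / L
    rel = pts - a
    perp = rel - np.outer(rel @ axis, axis)
    return float(np.max(np.linalg.norm(perp, axis=1)))


def point_segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from many ``points`` to the segment ``a``-``b``."""
    pts = np.atleast_2d(np.asarray(points, float))
    ab = np.asarray(b, float) - np.asarray(a, float)
    denom = float(ab @ ab)
    if denom < 1e-18:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


# --------------------------------------------------------------------------
# planar polygon triangulation (ear clipping) and mesh cutting
# --------------------------------------------------------------------------

def ear_clip(polygon: np.ndarray) -> np.ndarray:
    """Triangulate a simple 2D polygon by ear clipping.

    Returns an (m, 3) index array into ``polygon``.  Works for the convex
    or mildly concave cross-sections produced by plane cuts through
    tube-like bone meshes.
    """
    poly = np.asarray(polygon, float)
    n = len(poly)
    if n < 3:
        raise ValueError("polygon needs >= 3 vertices")
    # enforce counter-clockwise orientation
    area2 = np.sum(poly[:, 0] * np.roll(poly[:, 1], -1) - np.roll(poly[:, 0], -1) * poly[:, 1])
    order = list(range(n)) if area2 >= 0 else list(range(n - 1, -1, -1))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def point_in_tri(p, a, b, c):
        d1 = cross(a, b, p)
        d2 = cross(b, c, p)
        d3 = cross(c, a, p)
        return (d1 >= -1e-12) and (d2 >= -1e-12) and (d3 >= -1e-12)

    tris: list[tuple[int, int, int]] = []
    idx = order[:]
    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = poly[i0], poly[i1], poly[i2]
            if cross(a, b, c) <= 1e-14:  # reflex or degenerate corner
                continue
            ok = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                if point_in_tri(poly[j], a, b, c):
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
        if not clipped:  # numerically flat remainder: fan it
            break
    if len(idx) >= 3:
        for k in range(1, len(idx) - 1):
            tris.append((idx[0], idx[k], idx[k + 1]))
    return np.asarray(tris, dtype=int)


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex-index loops of the open boundary of ``mesh``."""
    edges = mesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        return []
    # adjacency walk; boundary vertices of a clean slice have degree 2
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    seen: set[tuple[int, int]] = set()
    loops = []
    for a0, b0 in boundary:
        a0, b0 = int(a0), int(b0)
        if (a0, b0) in seen:
            continue
        loop = [a0, b0]
        seen.add((a0, b0))
        seen.add((b0, a0))
        while True:
            prev, cur = loop[-2], loop[-1]
            nxts = [v for v in adj[cur] if v != prev and (cur, v) not in seen]
            if not nxts:
                break
            nxt = nxts[0]
            seen.add((cur, nxt))
            seen.add((nxt, cur))
            if nxt == loop[0]:
                break
            loop.append(nxt)
        if len(loop) >= 3:
            loops.append(np.asarray(loop, dtype=int))
    return loops


def cap_open_mesh(mesh: trimesh.Trimesh, plane: Plane) -> trimesh.Trimesh:
    """Close a plane-sliced open mesh by triangulating its boundary loops.

    Cap triangles are wound so their normals point along ``-plane.normal``
    (outward from the kept half-space, which lies on the +normal side).
    """
    loops = _boundary_loops(mesh)
    if not loops:
        return mesh
    u, v = plane.basis()
    verts = mesh.vertices
    new_faces = [mesh.faces]
    for loop in loops:
        pts3 = verts[loop]
        pts2 = np.stack([(pts3 - plane.anchor) @ u, (pts3 - plane.anchor) @ v], axis=1)
        tris = ear_clip(pts2)
        faces = loop[tris]
        # orient cap outward (away from the kept volume)
        e1 = verts[faces[:, 1]] - verts[faces[:, 0]]
        e2 = verts[faces[:, 2]] - verts[faces[:, 0]]
        nrm = np.cross(e1, e2).sum(axis=0)
        if nrm @ plane.normal > 0:
            faces = faces[:, ::-1]
        new_faces.append(faces)
    out = trimesh.Trimesh(vertices=verts.copy(), faces=np.vstack(new_faces), process=False)
    return out


def slice_mesh(mesh: trimesh.Trimesh, plane: Plane, keep_positive: bool = True) -> trimesh.Trimesh:
    """Cut ``mesh`` with ``plane`` and return the capped kept half.

    ``keep_positive`` keeps the half-space the plane normal points into.
    """
    normal = plane.normal if keep_positive else -plane.normal
    part = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=normal, plane_origin=plane.anchor, cap=False)
    if part is None or len(part.faces) == 0:
        raise ValueError("cut plane does not intersect the mesh (empty part)")
    # slicing splits triangles without welding the new intersection vertices;
    # merge them so the cut boundary chains into closed loops
    part = trimesh.Trimesh(vertices=part.vertices.copy(),
                           faces=part.faces.copy(), process=False)
    part.merge_vertices()
    return cap_open_mesh(part, Plane(plane.anchor, normal))
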