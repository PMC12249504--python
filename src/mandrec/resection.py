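"""Tumor-resection planning: osteotomy cut placement and defect classification.

Raw cut planes are snapped onto the nearest point of the registered
mandibular midline and aligned perpendicular to the local bone axis (plane
normal = midline tangent), then optionally moved along the midline or
rotated about their center.  Cutting partitions the mandible into resected
and residual parts, both closed along the cut faces.  The resulting defect
interval on the midline is classified in Jewer HCL terms using the
reference zone boundaries: C spans canine to canine, the L/H boundary sits
at the antegonial notch per side, and H absorbs L on the same side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import trimesh

from .errors import CutPlacementError
from .geometry import Plane, Polyline, rotation_about_axis, slice_mesh, unit

DEFAULT_SNAP_MAX_DISTANCE = 40.0  # mm

#: canonical ordering used to pick the side-agnostic HCL label
_LETTER_ORDER = {"H": 0, "L": 1, "C": 2}


@dataclass(frozen=True)
class CutPlane:
    """A planar osteotomy cut snapped to the midline.

    ``rotation`` records user re-orientation relative to the tangent-aligned
    frame so that moving the cut along the midline preserves it.
    """

    anchor: np.ndarray
    normal: np.ndarray
    midline_s: float
    extent: float = 30.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "anchor", np.asarray(self.anchor, float))
        object.__setattr__(self, "normal", unit(self.normal))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))

    @property
    def plane(self) -> Plane:
        return Plane(self.anchor, self.normal)


def snap_cut_to_midline(raw_anchor: np.ndarray, midline: Polyline,
                        max_distance: float = DEFAULT_SNAP_MAX_DISTANCE,
                        extent: float = 30.0) -> CutPlane:
    """Project a raw cut position onto the midline, tangent-aligned.

    The anchor becomes the closest midline point; the normal becomes the
    unit midline tangent there, making the cut face perpendicular to the
    local bone axis.  Idempotent.
    """
    raw_anchor = np.asarray(raw_anchor, float)
    s, point = midline.project_point(raw_anchor)
    if np.linalg.norm(raw_anchor - point) > max_distance:
        raise CutPlacementError(
            f"cut not near mandible: anchor is "
            f"{np.linalg.norm(raw_anchor - point):.1f} mm from the midline "
            f"(max {max_distance:.1f} mm)")
    return CutPlane(anchor=point, normal=midline.tangent_at(s), midline_s=s,
                    extent=extent)


def cut_at_s(midline: Polyline, s: float, extent: float = 30.0) -> CutPlane:
    """Cut plane at arc length ``s``, tangent-aligned (no user rotation)."""
    s = float(np.clip(s, 0.0, midline.length))
    return CutPlane(anchor=midline.point_at(s), normal=midline.tangent_at(s),
                    midline_s=s, extent=extent)


def move_cut(cut: CutPlane, delta_s: float, midline: Polyline) -> CutPlane:
    """Slide the cut along the midline by ``delta_s`` mm, re-snapping.

    Any prior user rotation is re-applied on top of the new tangent frame.
    Out-of-domain targets are clamped (with a warning recorded on the
    module logger rather than an exception).
    """
    s_new = cut.midline_s + delta_s
    clamped = float(np.clip(s_new, 0.0, midline.length))
    if clamped != s_new:
        import warnings
        warnings.warn(f"cut position clamped to midline domain at {clamped:.1f} mm",
                      stacklevel=2)
    tangent = midline.tangent_at(clamped)
    return CutPlane(anchor=midline.point_at(clamped),
                    normal=cut.rotation @ tangent,
                    midline_s=clamped, extent=cut.extent,
                    rotation=cut.rotation.copy())


def rotate_cut(cut: CutPlane, axis: str, angle_deg: float,
               midline: Polyline) -> CutPlane:
    """Rotate the cut about one of its in-plane axes through its center.

    Axes are taken from the tangent-aligned base frame at the cut's midline
    position, so rotations compose and invert exactly.
    """
    if axis not in ("in-plane-1", "in-plane-2"):
        raise ValueError("axis must be 'in-plane-1' or 'in-plane-2'")
    tangent = midline.tangent_at(cut.midline_s)
    u, v = Plane(cut.anchor, tangent).basis()
    R = rotation_about_axis(u if axis == "in-plane-1" else v, angle_deg)
    rotation = R @ cut.rotation
    return replace(cut, normal=rotation @ tangent, rotation=rotation)


# --------------------------------------------------------------------------
# mesh partitioning
# --------------------------------------------------------------------------

def _try_slice(mesh: trimesh.Trimesh, plane: Plane,
               keep_positive: bool) -> Optional[trimesh.Trimesh]:
    """Slice, returning None for an empty side and the input if untouched."""
    d = plane.signed_distance(mesh.vertices)
    sign = 1.0 if keep_positive else -1.0
    if np.all(sign * d <= 1e-9):
        return None
    if np.all(sign * d >= -1e-9):
        return mesh
    return slice_mesh(mesh, plane, keep_positive=keep_positive)


def cut_mandible(mandible_mesh: trimesh.Trimesh, cuts: list[CutPlane],
                 resected_side: Optional[str] = None,
                 midline: Optional[Polyline] = None
                 ) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Partition the mandible into (resected, residual) closed meshes.

    With two cuts the resected part is the stretch of bone between them;
    with one cut ``resected_side`` ("left" or "right") names the midline end
    that is removed.  Because the mandible is horseshoe-shaped, an infinite
    cut plane through one side can also intersect the contralateral side;
    like a finite saw blade, the cut only takes effect locally: the mesh is
    partitioned by the planes, split into connected components, and each
    component is attributed to resected or residual by the midline arc
    position of its centroid.  Both outputs are capped along the cut faces,
    so their volumes sum to the input volume exactly up to triangulation
    round-off.
    """
    if len(cuts) not in (1, 2):
        raise CutPlacementError("need 1 or 2 cut planes")
    for c in cuts:
        d = c.plane.signed_distance(mandible_mesh.vertices)
        if d.min() > -1e-9 or d.max() < 1e-9:
            raise CutPlacementError("cut plane does not intersect the mandible")
    if len(cuts) == 1 and resected_side not in ("left", "right"):
        raise CutPlacementError(
            "single-cut plans need resected_side 'left' or 'right'")

    ordered = sorted(cuts, key=lambda c: c.midline_s)
    pieces = [mandible_mesh]
    for cut in ordered:
        next_pieces = []
        for piece in pieces:
            for keep in (True, False):
                part = _try_slice(piece, cut.plane, keep)
                if part is not None and len(part.faces) > 0:
                    next_pieces.append(part)
        pieces = next_pieces

    components: list[trimesh.Trimesh] = []
    for piece in pieces:
        components.extend(piece.split(only_watertight=False))

    if midline is None:
        # reconstruct an attribution axis from the cut anchors alone:
        # fall back to signed distances (valid when planes cut once)
        def is_resected(comp: trimesh.Trimesh) -> bool:
            center = comp.center_mass
            if len(ordered) == 2:
                d1 = ordered[0].plane.signed_distance(center)
                d2 = ordered[1].plane.signed_distance(center)
                n1 = ordered[0].normal
                if n1 @ (ordered[1].anchor - ordered[0].anchor) < 0:
                    d1 = -d1
                n2 = ordered[1].normal
                if n2 @ (ordered[1].anchor - ordered[0].anchor) < 0:
                    d2 = -d2
                return d1 > 0 and d2 < 0
            d = ordered[0].plane.signed_distance(center)
            n = ordered[0].normal
            positive_is_left = n @ np.array([-1.0, 0.0, 0.0]) >= 0
            want_positive = (resected_side == "left") == positive_is_left
            return (d > 0) == want_positive
    else:
        s_cuts = [c.midline_s for c in ordered]

        def is_resected(comp: trimesh.Trimesh) -> bool:
            s_c, _ = midline.project_point(comp.center_mass)
            if len(ordered) == 2:
                return s_cuts[0] < s_c < s_cuts[1]
            return (s_c > s_cuts[0]) == (resected_side == "left")

    resected_parts = [c for c in components if is_resected(c)]
    residual_parts = [c for c in components if not is_resected(c)]
    if not resected_parts or not residual_parts:
        raise CutPlacementError("cuts do not separate the mandible into "
                                "resected and residual parts")
    resected = trimesh.util.concatenate(resected_parts)
    residual = trimesh.util.concatenate(residual_parts)
    return resected, residual


# --------------------------------------------------------------------------
# Jewer HCL classification
# --------------------------------------------------------------------------

def _zones(zone_boundaries: np.ndarray, total_length: float):
    b = np.asarray(zone_boundaries, float)
    return [
        (0.0, b[0], "H", "right"),
        (b[0], b[1], "L", "right"),
        (b[1], b[2], "C", "center"),
        (b[2], b[3], "L", "left"),
        (b[3], total_length, "H", "left"),
    ]


def classify_interval(defect_interval: tuple[float, float],
                      zone_boundaries: np.ndarray,
                      total_length: float) -> str:
    """HCL class of a midline arc-length interval.

    Letters are collected right-to-left over the intersected zones; H
    absorbs L on the same side; C appears once.  The label is canonicalized
    to the side-agnostic convention (LC rather than CL, HCL rather than
    LCH), matching clinical usage.
    """
    s_lo, s_hi = float(defect_interval[0]), float(defect_interval[1])
    if s_hi <= s_lo:
        raise CutPlacementError("empty defect interval")
    letters = []
    for a, b, letter, side in _zones(zone_boundaries, total_length):
        if min(s_hi, b) - max(s_lo, a) > 1e-9:
            letters.append((letter, side))
    if not letters:
        raise CutPlacementError("defect interval intersects no zone")
    for side in ("right", "left"):
        if ("H", side) in letters and ("L", side) in letters:
            letters.remove(("L", side))
    s = "".join(letter for letter, _ in letters)
    rev = s[::-1]
    key = lambda t: [_LETTER_ORDER[c] for c in t]
    return s if key(s) <= key(rev) else rev


@dataclass
class ResectionPlan:
    """One or two snapped cuts plus the induced mesh partition and class."""

    cuts: list[CutPlane]
    resected_mesh: trimesh.Trimesh
    residual_mesh: trimesh.Trimesh
    defect_interval: tuple[float, float]
    hcl_class: str
    resected_side: Optional[str] = None


def build_plan(mandible_mesh: trimesh.Trimesh, midline: Polyline,
               zone_boundaries: np.ndarray, cuts: list[CutPlane],
               resected_side: Optional[str] = None) -> ResectionPlan:
    """Assemble a classified resection plan from snapped cuts."""
    if len(cuts) == 2:
        c1, c2 = sorted(cuts, key=lambda c: c.midline_s)
        interval = (c1.midline_s, c2.midline_s)
    else:
        s = cuts[0].midline_s
        if resected_side == "left":
            interval = (s, midline.length)
        elif resected_side == "right":
            interval = (0.0, s)
        else:
            raise CutPlacementError(
                "single-cut plans need resected_side 'left' or 'right'")
    resected, residual = cut_mandible(mandible_mesh, cuts, resected_side,
                                      midline=midline)
    hcl = classify_interval(interval, zone_boundaries, midline.length)
    return ResectionPlan(cuts=list(cuts), resected_mesh=resected,
                         residual_mesh=residual, defect_interval=interval,
                         hcl_class=hcl, resected_side=resected_side)


def classify_defect(plan: ResectionPlan, zone_boundaries: np.ndarray,
                    total_length: float) -> str:
    """Classify an existing plan's defect interval (see classify_interval)."""
    return classify_interval(plan.defect_interval, zone_boundaries, total_length)
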