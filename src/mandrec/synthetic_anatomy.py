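"""Deterministic parametric anatomy for end-to-end testing without patient data.

Clinical inputs to fibula-flap planning are segmented surface meshes of the
mandible and fibulae; such datasets are rarely shareable.  This module
generates stand-ins with the features the pipeline relies on:

* a quasi-symmetric horseshoe mandible -- an elliptical cross-section swept
  along a planar body arc with near-vertical rami and capped condyles --
  carrying 14 named landmarks, a condyle-to-condyle midline polyline,
  zone boundaries for defect classification and a lateral direction field;
* a long, slightly curved prismatic fibula with a marked lateral face and a
  medially running vessel line;
* segmental defect scenarios (Jewer classes H, L, C, LC, LCL, HCL) with
  ground-truth resection planes for round-trip tests.

Everything is seeded and reproducible: identical specs give byte-identical
meshes and landmark coordinates.  Coordinates are millimetres in a RAS-like
frame: +x right, +y anterior, +z superior; the median plane is x = 0 for a
perfectly symmetric mandible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pydantic
import trimesh

from .errors import UnconstructibleScenarioError
from .geometry import Plane, Polyline, unit
from .io_formats import Landmark, LandmarkSet

#: The 14 named landmark sites shared by the reference model and generator.
LANDMARK_NAMES = [
    "pogonion",
    "gnathion",
    "mental_foramen_right", "mental_foramen_left",
    "canine_point_right", "canine_point_left",
    "gonion_right", "gonion_left",
    "antegonial_notch_right", "antegonial_notch_left",
    "coronoid_tip_right", "coronoid_tip_left",
    "condylion_right", "condylion_left",
]

_VERTEX_NOISE_MM = 0.02  # surface jitter amplitude driven by the seed


class MandibleSpec(pydantic.BaseModel):
    """Parameters of the parametric mandible (all lengths in mm)."""

    model_config = pydantic.ConfigDict(extra="forbid")

    body_arc_radius: float = 30.0
    body_height: float = 25.0
    ramus_height: float = 55.0
    intercondylar_width: float = 100.0
    asymmetry: float = 0.0
    mesh_resolution: float = 0.25  # vertices per mm^2
    seed: int = 0

    @pydantic.field_validator("body_arc_radius", "body_height", "ramus_height",
                              "intercondylar_width", "mesh_resolution")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    @pydantic.field_validator("asymmetry")
    @classmethod
    def _unit_interval(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        return v


class FibulaSpec(pydantic.BaseModel):
    """Parameters of the parametric fibula (lengths mm, azimuth degrees)."""

    model_config = pydantic.ConfigDict(extra="forbid")

    length: float = 240.0
    diameter: float = 12.0
    curvature: float = 0.0  # 1/mm, gentle bow of the shaft
    lateral_face_azimuth: float = 0.0
    vessel_offset: float = 5.0  # medial distance of the vessel line
    seed: int = 0

    @pydantic.field_validator("length", "diameter", "vessel_offset")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    @pydantic.field_validator("curvature")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("curvature must be >= 0")
        return v

    @pydantic.model_validator(mode="after")
    def _slender(self):
        if self.length <= 10 * self.diameter:
            raise ValueError("length must exceed 10 x diameter")
        return self


HclClass = Literal["H", "L", "C", "LC", "LCL", "HCL"]


class DefectScenario(pydantic.BaseModel):
    """A segmental defect to synthesize, in Jewer HCL terms."""

    model_config = pydantic.ConfigDict(extra="forbid")

    hcl_class: HclClass
    side: Literal["left", "right", "central"]
    arc_span: float = 0.0  # 0 selects a class-typical span

    @pydantic.model_validator(mode="after")
    def _side_consistent(self):
        central = {"C", "LCL"}
        if (self.hcl_class in central) != (self.side == "central"):
            raise ValueError(
                f"class {self.hcl_class} incompatible with side {self.side}")
        if self.arc_span < 0:
            raise ValueError("arc_span must be positive")
        return self


# --------------------------------------------------------------------------
# generated-anatomy containers
# --------------------------------------------------------------------------

@dataclass
class MandibleAnatomy:
    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    midline: Polyline
    zone_boundaries: np.ndarray  # 4 increasing arc lengths on the midline
    lateral_marking: np.ndarray  # outward unit direction per midline sample
    rigid_points: dict
    body_height: float
    spec: MandibleSpec


@dataclass
class FibulaAnatomy:
    mesh: trimesh.Trimesh
    axis: Polyline
    lateral_field: np.ndarray  # unit lateral-face direction per axis sample
    vessel: Polyline
    harvestable_length: float
    diameter: float
    spec: FibulaSpec


@dataclass
class GroundTruthResection:
    """Cut planes realizing a defect scenario, plus the intended interval."""

    planes: list
    s_values: list
    defect_interval: tuple
    resected_side: Optional[str]  # end removed by a single-cut plan


@dataclass
class PatientCase:
    mandible: MandibleAnatomy
    fibulae: dict
    scenario: DefectScenario
    ground_truth: GroundTruthResection

    @property
    def landmarks(self) -> LandmarkSet:
        return self.mandible.landmarks


# --------------------------------------------------------------------------
# mandible generation
# --------------------------------------------------------------------------

def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation
    return float(np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b))))


def _resample(points: np.ndarray, spacing: float) -> np.ndarray:
    line = Polyline(points)
    n = max(8, int(np.ceil(line.length / spacing)) + 1)
    return line.point_at(np.linspace(0.0, line.length, n))


def _right_half_centerline(spec: MandibleSpec) -> tuple[np.ndarray, dict]:
    """Centerline samples from the right condyle to the chin, plus feature points."""
    R = spec.body_arc_radius
    h = spec.ramus_height
    alpha_g = np.radians(-30.0)  # body-arc end (gonion) on the right

    gonion = np.array([R * np.cos(alpha_g), R * np.sin(alpha_g), 0.0])
    condyle = np.array([spec.intercondylar_width / 2.0, gonion[1], h])
    f = min(0.35 * h, 0.45 * R)  # corner-rounding extent

    ramus_dir = unit(gonion - condyle)
    p_a = gonion - f * ramus_dir  # on the ramus, above the gonion
    d_alpha = f / R
    alpha_b = alpha_g + d_alpha
    p_b = np.array([R * np.cos(alpha_b), R * np.sin(alpha_b), 0.0])

    pieces = []
    # ramus: condyle -> p_a
    t = np.linspace(0.0, 1.0, 24)[:, None]
    pieces.append(condyle + t * (p_a - condyle))
    # rounded gonial angle: quadratic Bezier p_a -> gonion -> p_b
    t = np.linspace(0.0, 1.0, 24)[1:, None]
    bez = ((1 - t) ** 2) * p_a + 2 * t * (1 - t) * gonion + (t ** 2) * p_b
    pieces.append(bez)
    # body arc: alpha_b -> 90 deg (chin)
    alphas = np.linspace(alpha_b, np.pi / 2.0, 96)[1:]
    arc = np.stack([R * np.cos(alphas), R * np.sin(alphas),
                    np.zeros_like(alphas)], axis=1)
    pieces.append(arc)

    centers = np.vstack(pieces)
    features = {
        "condylion": condyle,
        "gonion": gonion,
        "antegonial_notch": np.array([R * np.cos(np.radians(-20.0)),
                                      R * np.sin(np.radians(-20.0)), 0.0]),
        "canine_point": np.array([R * np.cos(np.radians(65.0)),
                                  R * np.sin(np.radians(65.0)), 0.0]),
        "mental_foramen": np.array([R * np.cos(np.radians(45.0)),
                                    R * np.sin(np.radians(45.0)), 0.0]),
        "coronoid_z": 0.85 * h,
    }
    return centers, features


def _asymmetry_warp(points: np.ndarray, asymmetry: float) -> np.ndarray:
    """Smooth unilateral scaling: inflates the right (+x) side, fixes the left."""
    pts = np.asarray(points, float).copy()
    if asymmetry == 0.0:
        return pts
    w = 0.5 * (1.0 + np.tanh(pts[..., 0] / 10.0))
    pts[..., 0] *= 1.0 + 0.08 * asymmetry * w
    return pts


def generate_mandible(spec: MandibleSpec) -> MandibleAnatomy:
    """Generate the parametric mandible with landmarks, midline and zones.

    The mesh is watertight and outward-oriented.  All 14 landmarks are mesh
    vertices, so they lie exactly on the surface.
    """
    a_h = spec.body_height / 2.0      # cross-section semi-height
    a_w = spec.body_height / 4.0      # cross-section semi-width

    right, feats = _right_half_centerline(spec)
    mirror = right[::-1].copy()
    mirror[:, 0] *= -1.0
    centers = np.vstack([right, mirror[1:]])  # chin appears once

    spacing = 1.0 / np.sqrt(spec.mesh_resolution)
    centers = _resample(centers, spacing)
    n_u = len(centers)
    perim = _ellipse_perimeter(a_w, a_h)
    n_theta = 12 * max(2, int(round(perim * np.sqrt(spec.mesh_resolution) / 12.0)))

    # frames: N1 = horizontal radial (outward), N2 = N1 x tangent (vertical in body)
    tangents = np.gradient(centers, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    radial = centers.copy()
    radial[:, 2] = 0.0
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    n2 = np.cross(radial, tangents)
    n2 /= np.linalg.norm(n2, axis=1, keepdims=True)

    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    rings = (centers[:, None, :]
             + a_w * cos_t[None, :, None] * radial[:, None, :]
             + a_h * sin_t[None, :, None] * n2[:, None, :])

    # spherical-ish condyle caps: shrinking rings pushed out along -/+ tangent
    cap_phis = np.radians([30.0, 60.0])
    r_cap = a_w

    def _cap(end_idx: int, outward: np.ndarray):
        cap_rings = []
        for phi in cap_phis:
            ring = (centers[end_idx]
                    + r_cap * np.sin(phi) * outward
                    + np.cos(phi) * (a_w * cos_t[:, None] * radial[end_idx]
                                     + a_h * sin_t[:, None] * n2[end_idx]))
            cap_rings.append(ring)
        pole = centers[end_idx] + r_cap * outward
        return cap_rings, pole

    start_rings, start_pole = _cap(0, -tangents[0])
    end_rings, end_pole = _cap(n_u - 1, tangents[-1])

    ring_stack = [start_rings[1], start_rings[0]] + [rings[i] for i in range(n_u)] \
        + [end_rings[0], end_rings[1]]
    verts = [start_pole[None, :]] + ring_stack + [end_pole[None, :]]
    vertices = np.vstack(verts)

    n_rings = len(ring_stack)
    ring_offset = 1  # pole 0 first

    faces = []
    # start pole fan
    first = ring_offset
    for j in range(n_theta):
        faces.append([0, first + j, first + (j + 1) % n_theta])
    # tube quads
    for i in range(n_rings - 1):
        r0 = ring_offset + i * n_theta
        r1 = r0 + n_theta
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            faces.append([r0 + j, r1 + j, r1 + j2])
            faces.append([r0 + j, r1 + j2, r0 + j2])
    # end pole fan
    last = ring_offset + (n_rings - 1) * n_theta
    pole_end = len(vertices) - 1
    for j in range(n_theta):
        faces.append([pole_end, last + (j + 1) % n_theta, last + j])

    vertices = _asymmetry_warp(vertices, spec.asymmetry)
    centers_w = _asymmetry_warp(centers, spec.asymmetry)
    start_pole_w = _asymmetry_warp(start_pole[None], spec.asymmetry)[0]
    end_pole_w = _asymmetry_warp(end_pole[None], spec.asymmetry)[0]

    # seeded surface jitter along the local ring direction
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, _VERTEX_NOISE_MM, size=(len(vertices), 1))
    ring_centers_full = np.vstack(
        [start_pole_w[None]]
        + [centers_w[0][None].repeat(n_theta, 0), centers_w[0][None].repeat(n_theta, 0)]
        + [centers_w[i][None].repeat(n_theta, 0) for i in range(n_u)]
        + [centers_w[-1][None].repeat(n_theta, 0), centers_w[-1][None].repeat(n_theta, 0)]
        + [end_pole_w[None]])
    radial_dirs = vertices - ring_centers_full
    norms = np.linalg.norm(radial_dirs, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    vertices = vertices + noise * radial_dirs / norms

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh = trimesh.Trimesh(vertices=vertices,
                               faces=np.asarray(faces)[:, ::-1], process=False)

    # ----- landmarks (as vertex indices -> exactly on the surface) -----
    def ring_near(point: np.ndarray) -> int:
        return int(np.argmin(np.linalg.norm(centers - point, axis=1)))

    def vert_index(ring_i: int, theta_deg: float) -> int:
        j = int(round((theta_deg % 360.0) / 360.0 * n_theta)) % n_theta
        return ring_offset + (2 + ring_i) * n_theta + j  # skip 2 start cap rings

    chin_i = ring_near(np.array([0.0, spec.body_arc_radius, 0.0]))

    def mirrored_ring(i: int) -> int:
        target = centers[i].copy()
        target[0] *= -1.0
        return ring_near(target)

    picks: dict[str, int] = {}
    picks["pogonion"] = vert_index(chin_i, 0.0)
    picks["gnathion"] = vert_index(chin_i, 300.0)
    for side, sgn in (("right", +1), ("left", -1)):
        g_i = ring_near(feats["gonion"]) if sgn > 0 else mirrored_ring(ring_near(feats["gonion"]))
        an_i = ring_near(feats["antegonial_notch"]) if sgn > 0 else mirrored_ring(ring_near(feats["antegonial_notch"]))
        ca_i = ring_near(feats["canine_point"]) if sgn > 0 else mirrored_ring(ring_near(feats["canine_point"]))
        mf_i = ring_near(feats["mental_foramen"]) if sgn > 0 else mirrored_ring(ring_near(feats["mental_foramen"]))
        # coronoid: ramus ring at ~85% height on this side
        side_mask = np.sign(centers[:, 0]) == sgn
        cand = np.where(side_mask)[0]
        co_i = int(cand[np.argmin(np.abs(centers[cand, 2] - feats["coronoid_z"]))])
        picks[f"gonion_{side}"] = vert_index(g_i, 0.0)
        picks[f"antegonial_notch_{side}"] = vert_index(an_i, 270.0)
        picks[f"canine_point_{side}"] = vert_index(ca_i, 0.0)
        picks[f"mental_foramen_{side}"] = vert_index(mf_i, 30.0)
        picks[f"coronoid_tip_{side}"] = vert_index(co_i, 90.0)
    picks["condylion_right"] = 0
    picks["condylion_left"] = len(vertices) - 1

    landmarks = LandmarkSet([
        Landmark(name, mesh.vertices[picks[name]].copy()) for name in LANDMARK_NAMES
    ])

    # ----- midline, zones, lateral marking -----
    midline_pts = np.vstack([start_pole_w[None], centers_w, end_pole_w[None]])
    midline = Polyline(midline_pts)
    cum = midline.arclengths

    def midline_s(ring_i: int) -> float:
        return float(cum[ring_i + 1])  # +1 for the prepended pole

    zone_boundaries = np.array([
        midline_s(ring_near(feats["antegonial_notch"])),
        midline_s(ring_near(feats["canine_point"])),
        midline_s(mirrored_ring(ring_near(feats["canine_point"]))),
        midline_s(mirrored_ring(ring_near(feats["antegonial_notch"]))),
    ])

    lat = midline_pts.copy()
    lat[:, 2] = 0.0
    norms = np.linalg.norm(lat, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    lateral_marking = lat / norms

    rigid_points = {name: mesh.vertices[picks[name]].copy()
                    for name in ("pogonion", "gonion_right", "gonion_left",
                                 "condylion_right", "condylion_left")}

    return MandibleAnatomy(
        mesh=mesh, landmarks=landmarks, midline=midline,
        zone_boundaries=zone_boundaries, lateral_marking=lateral_marking,
        rigid_points=rigid_points, body_height=spec.body_height, spec=spec)


# --------------------------------------------------------------------------
# fibula generation
# --------------------------------------------------------------------------

def generate_fibula(spec: FibulaSpec) -> FibulaAnatomy:
    """Generate the prismatic fibula with axis, lateral-face field and vessel."""
    L, r = spec.length, spec.diameter / 2.0
    n_u = max(16, int(np.ceil(L / 2.0)) + 1)
    t = np.linspace(0.0, L, n_u)  # arc-length parameter

    if spec.curvature > 0:
        rho = 1.0 / spec.curvature
        axis_pts = np.stack([rho * (1.0 - np.cos(t / rho)),
                             np.zeros_like(t),
                             rho * np.sin(t / rho)], axis=1)
        e_x = np.stack([np.cos(t / rho), np.zeros_like(t), -np.sin(t / rho)], axis=1)
    else:
        axis_pts = np.stack([np.zeros_like(t), np.zeros_like(t), t], axis=1)
        e_x = np.tile(np.array([1.0, 0.0, 0.0]), (n_u, 1))
    e_y = np.tile(np.array([0.0, 1.0, 0.0]), (n_u, 1))

    az = np.radians(spec.lateral_face_azimuth)
    lateral = np.cos(az) * e_x + np.sin(az) * e_y

    n_theta = 16
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    rings = (axis_pts[:, None, :]
             + r * np.cos(theta)[None, :, None] * e_x[:, None, :]
             + r * np.sin(theta)[None, :, None] * e_y[:, None, :])

    vertices = [axis_pts[0][None]]
    for i in range(n_u):
        vertices.append(rings[i])
    vertices.append(axis_pts[-1][None])
    vertices = np.vstack(vertices)

    rng = np.random.default_rng(spec.seed)
    jitter = rng.normal(0.0, 0.01, size=(len(vertices), 1))
    dirs = np.zeros_like(vertices)
    dirs[1:-1] = vertices[1:-1] - np.repeat(axis_pts, n_theta, axis=0)
    nz = np.linalg.norm(dirs, axis=1, keepdims=True)
    nz[nz < 1e-9] = 1.0
    vertices = vertices + jitter * dirs / nz

    faces = []
    for j in range(n_theta):
        faces.append([0, 1 + (j + 1) % n_theta, 1 + j])
    for i in range(n_u - 1):
        r0, r1 = 1 + i * n_theta, 1 + (i + 1) * n_theta
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            faces.append([r0 + j, r1 + j, r1 + j2])
            faces.append([r0 + j, r1 + j2, r0 + j2])
    last = 1 + (n_u - 1) * n_theta
    pole = len(vertices) - 1
    for j in range(n_theta):
        faces.append([pole, last + j, last + (j + 1) % n_theta])

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh = trimesh.Trimesh(vertices=vertices,
                               faces=np.asarray(faces)[:, ::-1], process=False)

    vessel = Polyline(axis_pts - spec.vessel_offset * lateral)
    return FibulaAnatomy(mesh=mesh, axis=Polyline(axis_pts), lateral_field=lateral,
                         vessel=vessel, harvestable_length=L,
                         diameter=spec.diameter, spec=spec)


# --------------------------------------------------------------------------
# defect scenarios
# --------------------------------------------------------------------------

_MARGIN = 2.0  # mm kept clear of zone boundaries when placing ground truth


def default_arc_span(hcl_class: str, mandible: MandibleAnatomy) -> float:
    """A class-typical defect span for the given mandible."""
    b = mandible.zone_boundaries
    S = mandible.midline.length
    spans = {
        "H": (S - b[3]) + 0.5 * (b[3] - b[2]),
        "L": 0.6 * (b[3] - b[2]),
        "C": 0.6 * (b[2] - b[1]),
        "LC": (b[2] - b[1]) * 0.5 + (b[3] - b[2]) * 0.5,
        "LCL": (b[2] - b[1]) + 0.5 * (b[1] - b[0]) + 0.5 * (b[3] - b[2]),
        "HCL": 0.5 * (b[2] + b[3]),  # single cut lands mid contralateral body
    }
    return float(spans[hcl_class])


def _ground_truth_interval(scenario: DefectScenario,
                           mandible: MandibleAnatomy) -> tuple[float, float, Optional[str]]:
    """Arc-length interval (and single-cut side, if any) realizing the class."""
    b = mandible.zone_boundaries
    S = mandible.midline.length
    span = scenario.arc_span or default_arc_span(scenario.hcl_class, mandible)
    cls, side = scenario.hcl_class, scenario.side

    def fail(msg):
        raise UnconstructibleScenarioError(
            f"cannot realize {cls}/{side} with span {span:.1f} mm: {msg}")

    if cls == "H":
        if side == "left":
            s_lo = S - span
            if not (b[2] + _MARGIN < s_lo < S - _MARGIN):
                fail("cut would leave the lateral-plus-ramus stretch on the left")
            return s_lo, S, "left"
        s_hi = span
        if not (_MARGIN < s_hi < b[1] - _MARGIN):
            fail("cut must stay right of the central zone")
        return 0.0, s_hi, "right"

    if cls == "HCL":
        if side == "right":
            s_hi = span
            if not (b[2] + _MARGIN < s_hi < b[3] - _MARGIN):
                fail("defect must end inside the contralateral body zone")
            return 0.0, s_hi, "right"
        s_lo = S - span
        if not (b[0] + _MARGIN < s_lo < b[1] - _MARGIN):
            fail("defect must end inside the contralateral body zone")
        return s_lo, S, "left"

    if cls == "L":
        lo, hi = (b[2], b[3]) if side == "left" else (b[0], b[1])
        center = 0.5 * (lo + hi)
    elif cls == "C":
        lo, hi = b[1], b[2]
        center = 0.5 * (lo + hi)
    elif cls == "LC":
        center = b[2] if side == "left" else b[1]
        lo = b[1] if side == "left" else b[0]
        hi = b[3] if side == "left" else b[2]
    elif cls == "LCL":
        center = 0.5 * (b[1] + b[2])
        lo, hi = b[0], b[3]
    else:  # pragma: no cover
        fail("unknown class")

    s_lo, s_hi = center - span / 2.0, center + span / 2.0
    if not (lo + _MARGIN < s_lo and s_hi < hi - _MARGIN):
        fail(f"interval [{s_lo:.1f}, {s_hi:.1f}] escapes the allowed zones "
             f"({lo:.1f}..{hi:.1f})")
    if cls == "LC":
        # must actually cross the canine boundary into both zones
        if not (s_lo < center - _MARGIN and s_hi > center + _MARGIN):
            fail("span too small to cross the canine boundary")
    if cls == "LCL":
        if not (s_lo < b[1] - _MARGIN and s_hi > b[2] + _MARGIN):
            fail("span too small to cover the central zone")
    return s_lo, s_hi, None


def generate_case(mandible_spec: MandibleSpec, fibula_spec: FibulaSpec,
                  scenario: DefectScenario) -> PatientCase:
    """Generate a full synthetic patient case with ground-truth resection."""
    mandible = generate_mandible(mandible_spec)
    left = generate_fibula(fibula_spec)
    right_spec = fibula_spec.model_copy(update={"seed": fibula_spec.seed + 1})
    right = generate_fibula(right_spec)

    s_lo, s_hi, resected_side = _ground_truth_interval(scenario, mandible)
    planes, s_values = [], []
    for s in ((s_lo, s_hi) if resected_side is None
              else ((s_hi,) if resected_side == "right" else (s_lo,))):
        planes.append(Plane(mandible.midline.point_at(s),
                            mandible.midline.tangent_at(s)))
        s_values.append(float(s))

    gt = GroundTruthResection(planes=planes, s_values=s_values,
                              defect_interval=(float(s_lo), float(s_hi)),
                              resected_side=resected_side)
    return PatientCase(mandible=mandible,
                       fibulae={"left_fibula": left, "right_fibula": right},
                       scenario=scenario, ground_truth=gt)
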