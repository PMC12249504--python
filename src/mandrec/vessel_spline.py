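"""Kochanek-Bartels spline reconstruction of vessel paths.

Peroneal arteries are marked by sparse, manually placed landmark points;
a smooth 3D course is obtained by interpolating them with a cubic Hermite
spline whose tangents carry the Kochanek-Bartels tension / bias /
continuity controls.  With all three parameters zero the curve reduces to
the Catmull-Rom spline.  Parameterization is uniform in the knot index
(the classic formulation); a chord-length option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MandrecError


@dataclass(frozen=True)
class KBSplineParams:
    tension: float = 0.0
    bias: float = 0.0
    continuity: float = 0.0
    samples_per_span: int = 16

    def __post_init__(self):
        if self.samples_per_span < 2:
            raise ValueError("samples_per_span must be >= 2")


def _kb_tangents(points: np.ndarray, t: float, b: float, c: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Outgoing and incoming tangents at every knot.

    Interior knots use the standard Kochanek-Bartels combination of the
    two neighbouring chords; endpoint tangents are one-sided differences
    scaled by (1 - tension).
    """
    n = len(points)
    d_prev = np.zeros_like(points)
    d_next = np.zeros_like(points)
    d_prev[1:] = points[1:] - points[:-1]
    d_next[:-1] = points[1:] - points[:-1]

    out = np.empty_like(points)
    inc = np.empty_like(points)
    # interior
    out[1:-1] = (((1 - t) * (1 + b) * (1 + c) / 2.0) * d_prev[1:-1]
                 + ((1 - t) * (1 - b) * (1 - c) / 2.0) * d_next[1:-1])
    inc[1:-1] = (((1 - t) * (1 + b) * (1 - c) / 2.0) * d_prev[1:-1]
                 + ((1 - t) * (1 - b) * (1 + c) / 2.0) * d_next[1:-1])
    # endpoints: one-sided
    out[0] = (1 - t) * d_next[0]
    inc[0] = out[0]
    out[-1] = (1 - t) * d_prev[-1]
    inc[-1] = out[-1]
    return out, inc


def kochanek_bartels(control_points: np.ndarray,
                     params: KBSplineParams = KBSplineParams(),
                     chord_length: bool = False) -> np.ndarray:
    """Sample the interpolating Kochanek-Bartels spline as a polyline.

    Returns an array of shape ``((n_spans * samples_per_span) + 1, 3)``
    sampled uniformly in parameter within each span; the curve passes
    through every control point exactly.

    Raises on fewer than 2 points or on duplicate consecutive points.
    """
    pts = np.asarray(control_points, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise MandrecError("control points must be an (n, 3) array")
    if len(pts) < 2:
        raise MandrecError("need at least 2 control points")
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chords < 1e-12):
        raise MandrecError("duplicate consecutive control points")

    out_tan, in_tan = _kb_tangents(pts, params.tension, params.bias,
                                   params.continuity)
    if chord_length:
        # rescale tangents so parameter velocity tracks chord length
        scale = np.ones(len(pts))
        scale[1:-1] = 2.0 * chords[1:] / (chords[:-1] + chords[1:])
        out_tan = out_tan * scale[:, None]
        scale_in = np.ones(len(pts))
        scale_in[1:-1] = 2.0 * chords[:-1] / (chords[:-1] + chords[1:])
        in_tan = in_tan * scale_in[:, None]

    m = params.samples_per_span
    u = np.linspace(0.0, 1.0, m + 1)
    h00 = 2 * u**3 - 3 * u**2 + 1
    h10 = u**3 - 2 * u**2 + u
    h01 = -2 * u**3 + 3 * u**2
    h11 = u**3 - u**2

    samples = []
    for i in range(len(pts) - 1):
        span = (h00[:, None] * pts[i] + h10[:, None] * out_tan[i]
                + h01[:, None] * pts[i + 1] + h11[:, None] * in_tan[i + 1])
        samples.append(span if i == len(pts) - 2 else span[:-1])
    return np.vstack(samples)


def read_vessel_csv(path) -> np.ndarray:
    """Ordered x,y,z control points, one per row (header optional)."""
    import csv
    from pathlib import Path

    rows = []
    with open(Path(path), newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                rows.append([float(row[0]), float(row[1]), float(row[2])])
            except ValueError:
                continue  # header line
    if len(rows) < 2:
        raise MandrecError(f"{path}: need at least 2 vessel control points")
    return np.asarray(rows, float)


def write_vessel_csv(points: np.ndarray, path) -> None:
    import csv
    from pathlib import Path

    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "z"])
        for row in np.asarray(points, float):
            writer.writerow([repr(float(v)) for v in row])
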