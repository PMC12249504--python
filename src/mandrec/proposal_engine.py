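"""Automatic calculation of reconstruction proposals.

For a classified resection and a selected reconstruction variant, the
engine places a chain of straight fibula segments bridging the defect:

1.  Chain endpoints are the intersections of the warped reference midline
    with the resection cut planes (for single-cut hemimandibulectomy-like
    plans, the free end of the defect interval is used as the second
    terminal).
2.  Interior knots are chosen on a uniform arc-length discretization of the
    warped midline (step ``config.midline_step``) by an exact search over
    all feasible knot placements, maximizing the weighted proposal score;
    per-pair segment deviations are precomputed so the search is a staged
    accumulation over prefix sums rather than a naive re-evaluation.  A
    local continuous refinement (coordinate descent along the midline with
    step halving) then polishes the knots.
3.  Inter-segment osteotomy planes are miter bisectors of adjacent segment
    axes; terminal planes coincide with the resection cuts.
4.  Segments map to disjoint harvest intervals on the donor fibula,
    allocated from the pedicle-proximal end and order-reversed when the
    recipient anastomosis side requires it.
5.  Each segment is rolled about its axis so the fibula's marked lateral
    face points outward while the vessels run medially; vessel-medial wins
    conflicts, with a warning.
6.  The transplant level (basal / middle / apical) vertically offsets the
    tooth-bearing knots.

The score is a weighted mean of four [0, 1] criteria -- midline fidelity,
symmetry, lateral-surface continuity and pedicle feasibility -- with the
balanced (all-equal) weighting as default.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import (DegenerateGeometryError, HarvestLengthError,
                     InfeasibleChainError)
from .geometry import (Plane, Polyline, perpendicular_vector,
                       point_segment_distances, rotation_about_axis, unit)
from .io_formats import EngineConfig
from .registration import ReferenceModel, estimate_median_plane
from .resection import CutPlane, ResectionPlan
from .synthetic_anatomy import FibulaAnatomy, PatientCase
from .variant_catalog import ReconstructionVariant

_ENDPOINT_TOL = 1e-6


# --------------------------------------------------------------------------
# data types
# --------------------------------------------------------------------------

@dataclass
class SegmentChain:
    """Ordered fibula segment chain bridging the defect.

    ``knots_s`` are the arc positions of the knots on the warped reference
    midline (projections, for knots displaced off the midline).
    """

    knots: np.ndarray            # (n+1, 3)
    knots_s: np.ndarray          # (n+1,)
    level_offset: float = 0.0
    roll_angles: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lateral_dirs: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self):
        self.knots = np.asarray(self.knots, float)
        self.knots_s = np.asarray(self.knots_s, float)
        if len(self.roll_angles) == 0:
            self.roll_angles = np.zeros(self.n_segments)
        if len(self.lateral_dirs) == 0:
            self.lateral_dirs = np.array(
                [perpendicular_vector(a) for a in self.segment_axes])

    @property
    def n_segments(self) -> int:
        return len(self.knots) - 1

    @property
    def segment_vectors(self) -> np.ndarray:
        return np.diff(self.knots, axis=0)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors, axis=1)

    @property
    def segment_axes(self) -> np.ndarray:
        v = self.segment_vectors
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def copy(self) -> "SegmentChain":
        return SegmentChain(self.knots.copy(), self.knots_s.copy(),
                            self.level_offset, self.roll_angles.copy(),
                            self.lateral_dirs.copy())


@dataclass(frozen=True)
class OsteotomyPlane:
    anchor: np.ndarray
    normal: np.ndarray
    kind: str  # junction_to_mandible | inter_segment

    def __post_init__(self):
        object.__setattr__(self, "anchor", np.asarray(self.anchor, float))
        object.__setattr__(self, "normal", unit(self.normal))


@dataclass
class HarvestPlan:
    """Disjoint intervals on the donor fibula axis, in fibula order."""

    intervals: list          # [(start_mm, end_mm), ...] increasing
    segment_order: list      # recipient segment index per interval
    gap: float               # saw kerf between intervals
    donor: str
    reversed_mapping: bool   # True when recipient order runs distal->pedicle

    def interval_for_segment(self, seg: int) -> tuple:
        return self.intervals[self.segment_order.index(seg)]


@dataclass
class ScoreBreakdown:
    midline_fidelity: float
    symmetry: float
    surface_continuity: float
    pedicle_feasibility: float
    weights: dict
    total: float

    def to_dict(self) -> dict:
        return {
            "midline_fidelity": self.midline_fidelity,
            "symmetry": self.symmetry,
            "surface_continuity": self.surface_continuity,
            "pedicle_feasibility": self.pedicle_feasibility,
            "weights": dict(self.weights),
            "total": self.total,
        }


@dataclass
class Proposal:
    variant: ReconstructionVariant
    chain: SegmentChain
    osteotomies: list
    harvest: HarvestPlan
    score: ScoreBreakdown
    warnings: list
    context: "DefectContext" = None  # planning context for refinement

    def to_dict(self) -> dict:
        return {
            "variant": {
                "variant_id": self.variant.variant_id,
                "n_segments": self.variant.n_segments,
                "donor": self.variant.donor,
                "pedicle_side": self.variant.pedicle_side,
                "skin_island": self.variant.skin_island,
            },
            "segment_lengths_mm": [round(float(v), 6)
                                   for v in self.chain.segment_lengths],
            "knots": [[round(float(x), 6) for x in k] for k in self.chain.knots],
            "level_offset_mm": round(float(self.chain.level_offset), 6),
            "roll_angles_deg": [round(float(a), 6) for a in self.chain.roll_angles],
            "osteotomy_planes": [
                {"anchor": [round(float(x), 6) for x in p.anchor],
                 "normal": [round(float(x), 9) for x in p.normal],
                 "kind": p.kind}
                for p in self.osteotomies
            ],
            "harvest": {
                "donor": self.harvest.donor,
                "intervals_mm": [[round(float(a), 6), round(float(b), 6)]
                                 for a, b in self.harvest.intervals],
                "segment_order": list(self.harvest.segment_order),
                "kerf_mm": self.harvest.gap,
                "reversed_mapping": self.harvest.reversed_mapping,
            },
            "score": {k: (round(v, 9) if isinstance(v, float) else v)
                      for k, v in self.score.to_dict().items()},
            "warnings": list(self.warnings),
        }


@dataclass
class ProposalResult:
    """Outcome per selected variant: a proposal or an explicit reason."""

    variant_id: str
    proposal: Optional[Proposal] = None
    error: Optional[str] = None

    def to_dict(self) -> dict:
        if self.proposal is not None:
            return self.proposal.to_dict()
        return {"variant": {"variant_id": self.variant_id}, "error": self.error}


# --------------------------------------------------------------------------
# defect context
# --------------------------------------------------------------------------

@dataclass
class DefectContext:
    """Everything chain fitting and scoring need about one defect."""

    midline: Polyline
    s_lo: float
    s_hi: float
    end_planes: tuple            # (Plane, Plane) at the two terminals
    samples_s: np.ndarray        # grid over [s_lo, s_hi], step = midline_step
    ref_pts: np.ndarray          # midline points at samples_s
    mirror_pts: np.ndarray       # mirrored contralateral targets
    outward_center: np.ndarray   # dental-arch centroid (roll target origin)
    up_at: object                # callable s -> unit vertical direction
    body_zone: tuple             # (s_start, s_end) of the tooth-bearing part
    config: EngineConfig
    plan: ResectionPlan = None
    warped: ReferenceModel = None
    case: PatientCase = None
    _pair_cache: tuple = field(default=None, repr=False, compare=False)


def _endpoint_s(midline: Polyline, cut: CutPlane) -> float:
    crossings = midline.intersect_plane(cut.plane)
    if not crossings:
        return float(cut.midline_s)
    return float(min(crossings, key=lambda s: abs(s - cut.midline_s)))


def build_defect_context(warped: ReferenceModel, plan: ResectionPlan,
                         config: EngineConfig) -> DefectContext:
    """Assemble the fitting/scoring context from registration + resection."""
    midline = warped.midline
    S = midline.length
    cuts = sorted(plan.cuts, key=lambda c: c.midline_s)
    if len(cuts) == 2:
        s_lo = _endpoint_s(midline, cuts[0])
        s_hi = _endpoint_s(midline, cuts[1])
        planes = (cuts[0].plane, cuts[1].plane)
    else:
        s_cut = _endpoint_s(midline, cuts[0])
        if plan.resected_side == "left":
            s_lo, s_hi = s_cut, S
            planes = (cuts[0].plane,
                      Plane(midline.point_at(S), midline.tangent_at(S)))
        else:
            s_lo, s_hi = 0.0, s_cut
            planes = (Plane(midline.point_at(0.0), midline.tangent_at(0.0)),
                      cuts[0].plane)
    if s_hi - s_lo < 2 * config.min_segment_length:
        raise InfeasibleChainError(
            f"defect arc {s_hi - s_lo:.1f} mm too short to plan")

    n = max(8, int(np.ceil((s_hi - s_lo) / config.midline_step)) + 1)
    samples_s = np.linspace(s_lo, s_hi, n)
    ref_pts = midline.point_at(samples_s)

    median = estimate_median_plane(warped.landmarks)
    mirror_pts = median.reflect_points(midline.point_at(S - samples_s))

    b = warped.zone_boundaries
    body_s = np.linspace(b[0], b[3], 64)
    outward_center = midline.point_at(body_s).mean(axis=0)

    marking = np.asarray(warped.lateral_marking, float)
    cum = midline.arclengths

    def up_at(s: float) -> np.ndarray:
        lat = np.array([np.interp(s, cum, marking[:, k]) for k in range(3)])
        tan = midline.tangent_at(float(s))
        v = np.cross(unit(lat), tan)
        nv = np.linalg.norm(v)
        return v / nv if nv > 1e-9 else np.array([0.0, 0.0, 1.0])

    return DefectContext(midline=midline, s_lo=s_lo, s_hi=s_hi,
                         end_planes=planes, samples_s=samples_s,
                         ref_pts=ref_pts, mirror_pts=mirror_pts,
                         outward_center=outward_center, up_at=up_at,
                         body_zone=(float(b[0]), float(b[3])), config=config,
                         plan=plan, warped=warped)


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def _projected_outward(axis: np.ndarray, midpoint: np.ndarray,
                       center: np.ndarray) -> np.ndarray:
    """Outward roll target: away from the dental-arch centroid, normal to axis."""
    out = midpoint - center
    out = out - (out @ axis) * axis
    n = np.linalg.norm(out)
    if n < 1e-9:
        return perpendicular_vector(axis)
    return out / n


def _sample_assignment(knots_s: np.ndarray, samples_s: np.ndarray) -> np.ndarray:
    """Segment index per midline sample, split at interior knot arc positions."""
    return np.clip(np.searchsorted(knots_s[1:-1], samples_s, side="right"),
                   0, len(knots_s) - 2)


def chain_component_scores(chain: SegmentChain, ctx: DefectContext,
                           lateral_dirs: Optional[np.ndarray] = None
                           ) -> tuple[float, float, float]:
    """(midline_fidelity, symmetry, surface_continuity) of a chain.

    Midline fidelity and symmetry are exponential decays of the mean
    distance between the defect midline samples (resp. their mirrored
    contralateral targets) and the chain, with samples matched to segments
    by arc interval.  Surface continuity is the mean junction cosine of
    adjacent lateral-face directions, clamped to [0, 1].
    """
    cfg = ctx.config
    seg_idx = _sample_assignment(chain.knots_s, ctx.samples_s)
    d_mid = np.empty(len(ctx.samples_s))
    d_sym = np.empty(len(ctx.samples_s))
    for j in range(chain.n_segments):
        mask = seg_idx == j
        if not np.any(mask):
            continue
        a, b = chain.knots[j], chain.knots[j + 1]
        d_mid[mask] = point_segment_distances(ctx.ref_pts[mask], a, b)
        d_sym[mask] = point_segment_distances(ctx.mirror_pts[mask], a, b)
    s_m = float(np.exp(-np.mean(d_mid) / cfg.tau_midline))
    s_s = float(np.exp(-np.mean(d_sym) / cfg.tau_symmetry))

    if chain.n_segments < 2:
        s_c = 1.0
    else:
        if lateral_dirs is None:
            axes = chain.segment_axes
            mids = 0.5 * (chain.knots[:-1] + chain.knots[1:])
            lateral_dirs = np.array([
                _projected_outward(axes[j], mids[j], ctx.outward_center)
                for j in range(chain.n_segments)])
        cosines = np.einsum("ij,ij->i", lateral_dirs[:-1], lateral_dirs[1:])
        s_c = float(np.clip(np.mean(np.clip(cosines, 0.0, 1.0)), 0.0, 1.0))
    return s_m, s_s, s_c


def pedicle_feasibility_score(chain: SegmentChain, variant: ReconstructionVariant,
                              warped: ReferenceModel, ctx: DefectContext) -> float:
    """1 while the pedicle end reaches the anastomosis site, decaying beyond."""
    cfg = ctx.config
    pedicle_knot = (chain.knots[0] if variant.pedicle_side == "right"
                    else chain.knots[-1])
    site = warped.rigid_points.get(f"gonion_{variant.pedicle_side}")
    if site is None:
        return 1.0
    d = float(np.linalg.norm(pedicle_knot - site))
    if d <= cfg.pedicle_max_length:
        return 1.0
    return float(np.exp(-(d - cfg.pedicle_max_length) / 20.0))


def combine_scores(components: dict, weights: dict) -> float:
    """Normalized weighted mean over the enabled (weight > 0) criteria."""
    active = {k: w for k, w in weights.items() if w > 0}
    if not active:
        raise DegenerateGeometryError("all score weights are zero")
    total = sum(w * components[k] for k, w in active.items())
    return float(total / sum(active.values()))


def score_proposal(proposal: Proposal, warped: ReferenceModel,
                   weights: Optional[dict] = None) -> ScoreBreakdown:
    """Recompute the full weighted score breakdown of a proposal."""
    ctx = proposal.context
    w = dict(weights or ctx.config.weights)
    s_m, s_s, s_c = chain_component_scores(
        proposal.chain, ctx, lateral_dirs=proposal.chain.lateral_dirs)
    s_p = pedicle_feasibility_score(proposal.chain, proposal.variant, warped, ctx)
    comps = {"midline_fidelity": s_m, "symmetry": s_s,
             "surface_continuity": s_c, "pedicle_feasibility": s_p}
    return ScoreBreakdown(midline_fidelity=s_m, symmetry=s_s,
                          surface_continuity=s_c, pedicle_feasibility=s_p,
                          weights=w, total=combine_scores(comps, w))


# --------------------------------------------------------------------------
# chain fitting
# --------------------------------------------------------------------------

def _chain_from_s(ctx: DefectContext, interior_s: np.ndarray) -> SegmentChain:
    knots_s = np.concatenate([[ctx.s_lo], np.asarray(interior_s, float),
                              [ctx.s_hi]])
    knots = ctx.midline.point_at(knots_s)
    # terminals sit exactly on the cut planes
    knots[0] = ctx.end_planes[0].project(knots[0])
    knots[-1] = ctx.end_planes[1].project(knots[-1])
    return SegmentChain(knots=knots, knots_s=knots_s)


def _score_placement(ctx: DefectContext, interior_s: np.ndarray,
                     weights: dict, s_p: float) -> float:
    chain = _chain_from_s(ctx, interior_s)
    if np.any(chain.segment_lengths < ctx.config.min_segment_length):
        return -np.inf
    s_m, s_s, s_c = chain_component_scores(chain, ctx)
    comps = {"midline_fidelity": s_m, "symmetry": s_s,
             "surface_continuity": s_c, "pedicle_feasibility": s_p}
    return combine_scores(comps, weights)


def _pair_tables(ctx: DefectContext):
    """Per-(i, j) segment tables over the sample grid (cached per context).

    ``sum_mid[i, j]`` / ``sum_sym[i, j]``: summed distances of samples
    ``i..j-1`` to the segment joining grid points i and j (the terminal
    sample K-1 is accounted separately); ``length[i, j]``: chord length;
    ``lat[i, j]``: projected-outward lateral direction of the segment.
    """
    if ctx._pair_cache is not None:
        return ctx._pair_cache
    pts = ctx.midline.point_at(ctx.samples_s)
    pts[0] = ctx.end_planes[0].project(pts[0])
    pts[-1] = ctx.end_planes[1].project(pts[-1])
    K = len(pts)
    sum_mid = np.zeros((K, K))
    sum_sym = np.zeros((K, K))
    length = np.zeros((K, K))
    lat = np.zeros((K, K, 3))
    for i in range(K - 1):
        for j in range(i + 1, K):
            a, b = pts[i], pts[j]
            v = b - a
            L = np.linalg.norm(v)
            length[i, j] = L
            if L < 1e-9:
                continue
            axis = v / L
            mid = 0.5 * (a + b)
            lat[i, j] = _projected_outward(axis, mid, ctx.outward_center)
            sl = slice(i, j)
            sum_mid[i, j] = point_segment_distances(ctx.ref_pts[sl], a, b).sum()
            sum_sym[i, j] = point_segment_distances(ctx.mirror_pts[sl], a, b).sum()
    # terminal sample K-1 contributions (assigned to the last segment)
    tail_mid = np.zeros((K,))
    tail_sym = np.zeros((K,))
    for i in range(K - 1):
        tail_mid[i] = point_segment_distances(ctx.ref_pts[-1:], pts[i], pts[-1])[0]
        tail_sym[i] = point_segment_distances(ctx.mirror_pts[-1:], pts[i], pts[-1])[0]
    ctx._pair_cache = (pts, sum_mid, sum_sym, length, lat, tail_mid, tail_sym)
    return ctx._pair_cache


def _combo_blocks(K: int, m: int, block: int = 200_000):
    """Yield (combos, ...) index arrays of strictly increasing interior picks.

    Candidates range over 1..K-2 (grid interior).  Lexicographic order, so
    the first maximum is the deterministic (lowest-index) tie-break.
    """
    cand = np.arange(1, K - 1)
    if m == 0:
        yield np.zeros((1, 0), dtype=int)
        return
    if m == 1:
        yield cand[:, None]
        return
    if m == 2:
        a, b = np.triu_indices(len(cand), k=1)
        combos = np.stack([cand[a], cand[b]], axis=1)
        for i in range(0, len(combos), block):
            yield combos[i:i + block]
        return
    if m == 3:
        for first in cand:
            rest = cand[cand > first]
            if len(rest) < 2:
                continue
            a, b = np.triu_indices(len(rest), k=1)
            combos = np.stack([np.full(len(a), first), rest[a], rest[b]], axis=1)
            for i in range(0, len(combos), block):
                yield combos[i:i + block]
        return
    raise InfeasibleChainError(
        f"{m + 1} segments exceed the supported interior-knot search")


def fit_segment_chain(ctx: DefectContext, n_segments: int,
                      weights: Optional[dict] = None,
                      pedicle_score: float = 1.0,
                      refine: Optional[bool] = None) -> SegmentChain:
    """Optimal segment chain for the defect with ``n_segments`` segments.

    Interior knots are chosen on the midline discretization to maximize the
    weighted score (exact search over all feasible placements), subject to
    every segment being at least ``config.min_segment_length`` long; ties
    break to the lowest knot indices.  ``refine`` enables the continuous
    coordinate-descent polish (defaults to ``config.refine_continuous``).
    """
    cfg = ctx.config
    if n_segments < 1:
        raise InfeasibleChainError("n_segments must be >= 1")
    if n_segments > cfg.max_segments:
        raise InfeasibleChainError(
            f"{n_segments} segments exceed the configured maximum of "
            f"{cfg.max_segments}")
    arc = ctx.s_hi - ctx.s_lo
    if arc <= n_segments * cfg.min_segment_length:
        raise InfeasibleChainError(
            f"defect arc {arc:.1f} mm cannot host {n_segments} segments of "
            f">= {cfg.min_segment_length:.1f} mm (min segment length violated)")
    w = dict(weights or cfg.weights)
    active = {k: v for k, v in w.items() if v > 0}
    if not active:
        raise DegenerateGeometryError("all score weights are zero")
    W = sum(active.values())

    if n_segments == 1:
        chain = _chain_from_s(ctx, np.zeros(0))
        if np.any(chain.segment_lengths < cfg.min_segment_length):
            raise InfeasibleChainError("chord shorter than min segment length")
        return chain

    pts, sum_mid, sum_sym, length, lat, tail_mid, tail_sym = _pair_tables(ctx)
    K = len(pts)
    N = float(len(ctx.samples_s))
    m = n_segments - 1
    w_m = active.get("midline_fidelity", 0.0)
    w_s = active.get("symmetry", 0.0)
    w_c = active.get("surface_continuity", 0.0)
    w_p = active.get("pedicle_feasibility", 0.0)

    best_score = -np.inf
    best_combo = None
    for combos in _combo_blocks(K, m):
        cols = [np.zeros(len(combos), dtype=int)] + \
            [combos[:, k] for k in range(m)] + \
            [np.full(len(combos), K - 1, dtype=int)]
        # feasibility: every chord >= min segment length
        ok = np.ones(len(combos), dtype=bool)
        for a, b in zip(cols[:-1], cols[1:]):
            ok &= length[a, b] >= cfg.min_segment_length
        if not np.any(ok):
            continue
        A = np.zeros(len(combos))
        B = np.zeros(len(combos))
        for a, b in zip(cols[:-1], cols[1:]):
            A += sum_mid[a, b]
            B += sum_sym[a, b]
        A += tail_mid[cols[-2]]
        B += tail_sym[cols[-2]]
        s_m = np.exp(-(A / N) / cfg.tau_midline)
        s_s = np.exp(-(B / N) / cfg.tau_symmetry)
        cos_sum = np.zeros(len(combos))
        for (a, b), (b2, c) in zip(zip(cols[:-2], cols[1:-1]),
                                   zip(cols[1:-1], cols[2:])):
            cos_sum += np.clip(np.einsum("ij,ij->i", lat[a, b], lat[b2, c]),
                               0.0, 1.0)
        s_c = np.clip(cos_sum / m, 0.0, 1.0)
        total = (w_m * s_m + w_s * s_s + w_c * s_c + w_p * pedicle_score) / W
        total[~ok] = -np.inf
        k = int(np.argmax(total))
        if total[k] > best_score:
            best_score = float(total[k])
            best_combo = combos[k].copy()
    if best_combo is None:
        raise InfeasibleChainError(
            "no feasible interior-knot placement (min segment length violated)")

    interior_s = ctx.samples_s[best_combo]
    if refine is None:
        refine = cfg.refine_continuous
    if refine:
        interior_s = _refine_interior(ctx, interior_s, w, pedicle_score)
    return _chain_from_s(ctx, interior_s)


def _refine_interior(ctx: DefectContext, interior_s: np.ndarray,
                     weights: dict, s_p: float) -> np.ndarray:
    """Coordinate descent on interior knot arc positions, step halving."""
    cfg = ctx.config
    s = np.asarray(interior_s, float).copy()
    best = _score_placement(ctx, s, weights, s_p)
    step = cfg.midline_step / 2.0
    while step >= cfg.refine_min_step:
        improved = True
        sweeps = 0
        while improved and sweeps < 25:
            improved = False
            sweeps += 1
            for k in range(len(s)):
                for delta in (step, -step):
                    trial = s.copy()
                    trial[k] = trial[k] + delta
                    lo = ctx.s_lo if k == 0 else trial[k - 1]
                    hi = ctx.s_hi if k == len(s) - 1 else trial[k + 1]
                    if not (lo < trial[k] < hi):
                        continue
                    val = _score_placement(ctx, trial, weights, s_p)
                    if val > best + 1e-15:
                        best, s = val, trial
                        improved = True
        step /= 2.0
    return s


# --------------------------------------------------------------------------
# osteotomies, harvest, orientation, level
# --------------------------------------------------------------------------

def compute_osteotomy_planes(chain: SegmentChain,
                             end_planes: tuple) -> list:
    """Terminal planes = resection planes; interior planes = miter bisectors."""
    axes = chain.segment_axes
    planes = [OsteotomyPlane(end_planes[0].anchor, end_planes[0].normal,
                             "junction_to_mandible")]
    for j in range(chain.n_segments - 1):
        bis = axes[j] + axes[j + 1]
        if np.linalg.norm(bis) < 1e-9:
            raise DegenerateGeometryError(
                f"segments {j + 1} and {j + 2} are anti-parallel; "
                "miter plane undefined")
        planes.append(OsteotomyPlane(chain.knots[j + 1], unit(bis),
                                     "inter_segment"))
    planes.append(OsteotomyPlane(end_planes[1].anchor, end_planes[1].normal,
                                 "junction_to_mandible"))
    return planes


def plan_harvest(chain: SegmentChain, fibula: FibulaAnatomy, donor: str,
                 pedicle_side: str, kerf: float = 1.0) -> HarvestPlan:
    """Map chain segments to disjoint harvest intervals on the donor fibula.

    Intervals are allocated contiguously from the pedicle-proximal end
    (axis position 0).  The recipient chain runs right-to-left; when the
    anastomosis is on the left, the mapping is reversed so the vessel end
    of the harvested strip lands next to the anastomosis side.
    """
    lengths = chain.segment_lengths
    n = len(lengths)
    needed = float(lengths.sum() + kerf * (n - 1))
    avail = fibula.harvestable_length
    if needed > avail + 1e-9:
        raise HarvestLengthError(
            f"donor fibula too short: need {needed:.1f} mm, have "
            f"{avail:.1f} mm (shortfall {needed - avail:.1f} mm)",
            shortfall_mm=needed - avail)
    reversed_mapping = pedicle_side == "left"
    seg_order = list(range(n - 1, -1, -1)) if reversed_mapping else list(range(n))
    intervals = []
    cursor = 0.0
    for seg in seg_order:
        intervals.append((cursor, cursor + float(lengths[seg])))
        cursor += float(lengths[seg]) + kerf
    return HarvestPlan(intervals=intervals, segment_order=seg_order,
                       gap=kerf, donor=donor, reversed_mapping=reversed_mapping)


def orient_segments(chain: SegmentChain, fibula: FibulaAnatomy,
                    harvest: HarvestPlan, ctx: DefectContext
                    ) -> tuple[np.ndarray, np.ndarray, list]:
    """Roll each segment so the lateral face points outward, vessels medial.

    Returns (roll_angles_deg, lateral_dirs, warnings).  The roll target is
    the direction away from the dental-arch centroid, normal to the segment
    axis.  If the fibula's vessel line would end up lateral, the roll backs
    off to the nearest vessel-medial orientation and a warning is emitted.
    """
    axes = chain.segment_axes
    mids = 0.5 * (chain.knots[:-1] + chain.knots[1:])
    rolls = np.zeros(chain.n_segments)
    lat_dirs = np.zeros((chain.n_segments, 3))
    warn: list[str] = []
    cum = fibula.axis.arclengths
    for j in range(chain.n_segments):
        u = axes[j]
        ref0 = perpendicular_vector(u)
        target = _projected_outward(u, mids[j], ctx.outward_center)
        # signed roll from the canonical frame vector to the target
        cosr = float(np.clip(ref0 @ target, -1.0, 1.0))
        sinr = float(np.cross(ref0, target) @ u)
        roll = np.degrees(np.arctan2(sinr, cosr))
        lateral = target

        # vessel offset direction relative to the lateral face, measured on
        # the harvested interval of the donor bone
        a, b = harvest.interval_for_segment(j)
        t_mid = 0.5 * (a + b)
        lat_f = np.array([np.interp(t_mid, cum, fibula.lateral_field[:, k])
                          for k in range(3)])
        axis_pt = fibula.axis.point_at(t_mid)
        vessel_pt = fibula.vessel.point_at(
            fibula.vessel.arclengths[-1] * t_mid / max(cum[-1], 1e-9))
        v_dir = vessel_pt - axis_pt
        v_dir = v_dir - (v_dir @ fibula.axis.tangent_at(t_mid)) * \
            fibula.axis.tangent_at(t_mid)
        v_dir = unit(v_dir) if np.linalg.norm(v_dir) > 1e-9 else -lat_f
        cosg = float(np.clip(unit(lat_f) @ v_dir, -1.0, 1.0))
        tang = fibula.axis.tangent_at(t_mid)
        sing = float(np.cross(unit(lat_f), v_dir) @ tang)
        gamma = np.degrees(np.arctan2(sing, cosg))  # vessel azimuth vs lateral

        placed_vessel = rotation_about_axis(u, gamma) @ lateral
        if placed_vessel @ target > 1e-9:
            # conflict: vessel would run lateral; rotate to the nearest
            # orientation with the vessel exactly on the medial boundary
            back = 90.0 - abs(180.0 - abs(gamma)) + 1e-6
            sign = -np.sign(float(np.cross(lateral, placed_vessel) @ u)) or 1.0
            roll += sign * back
            lateral = rotation_about_axis(u, sign * back) @ lateral
            warn.append(
                f"segment {j + 1}: lateral-face orientation reduced to keep "
                "the vessels medial")
        rolls[j] = roll
        lat_dirs[j] = lateral
    return rolls, lat_dirs, warn


def level_offset_mm(level: str, apical_offset: float, fibula_diameter: float
                    ) -> float:
    """Vertical transplant offset for a named level.

    basal = 0; apical lifts the segment top edge to the available body
    height; middle is halfway.
    """
    avail = max(0.0, apical_offset - fibula_diameter)
    return {"basal": 0.0, "middle": avail / 2.0, "apical": avail}[level]


def apply_level(chain: SegmentChain, offset: float, ctx: DefectContext
                ) -> SegmentChain:
    """Translate tooth-bearing knots vertically to ``offset`` (absolute).

    Knots whose midline position falls in the body zone move along the
    local vertical; terminal knots stay on their cut planes (the
    translation is projected into the plane).
    """
    delta = float(offset) - chain.level_offset
    out = chain.copy()
    if delta == 0.0:
        out.level_offset = float(offset)
        return out
    lo, hi = ctx.body_zone
    for k in range(len(out.knots)):
        s_k = out.knots_s[k]
        if not (lo <= s_k <= hi):
            continue
        t = delta * ctx.up_at(s_k)
        if k == 0:
            t = t - (t @ ctx.end_planes[0].normal) * ctx.end_planes[0].normal
        elif k == len(out.knots) - 1:
            t = t - (t @ ctx.end_planes[1].normal) * ctx.end_planes[1].normal
        out.knots[k] = out.knots[k] + t
    out.level_offset = float(offset)
    return out


def check_short_segments(chain: SegmentChain, threshold: float = 2.5) -> list:
    """Warnings for segments at or below the alert threshold (inclusive)."""
    out = []
    for j, L in enumerate(chain.segment_lengths):
        if L <= threshold:
            out.append(f"segment {j + 1} length {L:.2f} mm <= "
                       f"{threshold:.1f} mm alert threshold")
    return out


# --------------------------------------------------------------------------
# proposal assembly
# --------------------------------------------------------------------------

def assemble_proposal(variant: ReconstructionVariant, chain: SegmentChain,
                      ctx: DefectContext, warped: ReferenceModel,
                      case: PatientCase, config: EngineConfig) -> Proposal:
    """Attach osteotomies, harvest, orientation, level and score to a chain."""
    ctx.warped = warped
    ctx.case = case
    fibula = case.fibulae[variant.donor]
    harvest = plan_harvest(chain, fibula, variant.donor, variant.pedicle_side,
                           kerf=config.kerf)
    rolls, lat_dirs, orient_warnings = orient_segments(chain, fibula, harvest, ctx)
    chain = replace(chain.copy(), roll_angles=rolls, lateral_dirs=lat_dirs)
    offset = level_offset_mm(config.level, warped.apical_offset, fibula.diameter)
    if config.level != "basal":
        chain = apply_level(chain, offset, ctx)
    osteotomies = compute_osteotomy_planes(chain, ctx.end_planes)
    warnings = list(orient_warnings)
    warnings += check_short_segments(chain, config.short_segment_threshold)
    proposal = Proposal(variant=variant, chain=chain, osteotomies=osteotomies,
                        harvest=harvest, score=None, warnings=warnings,
                        context=ctx)
    proposal.score = score_proposal(proposal, warped)
    return proposal


def export_segment_meshes(proposal: Proposal, fibula: FibulaAnatomy) -> list:
    """Solid meshes of the placed segments, clipped by their osteotomy planes.

    Each segment is a circular prism of the fibula's diameter swept along
    the segment axis and mitre-clipped at both ends, mirroring how the
    harvested bone is trimmed.
    """
    import trimesh

    from .geometry import slice_mesh as _slice

    meshes = []
    r = fibula.diameter / 2.0
    ext = max(2.0 * r, 4.0)
    for j in range(proposal.chain.n_segments):
        a = proposal.chain.knots[j]
        b = proposal.chain.knots[j + 1]
        axis = unit(b - a)
        prism = trimesh.creation.cylinder(
            radius=r, segment=(a - ext * axis, b + ext * axis), sections=24)
        mid = 0.5 * (a + b)
        for plane in (proposal.osteotomies[j], proposal.osteotomies[j + 1]):
            p = Plane(plane.anchor, plane.normal)
            keep = bool(p.signed_distance(mid) > 0)
            prism = _slice(prism, p, keep_positive=keep)
        meshes.append(prism)
    return meshes


def calculate_proposals(plan: ResectionPlan,
                        variants: list[ReconstructionVariant],
                        warped: ReferenceModel, case: PatientCase,
                        config: EngineConfig) -> list[ProposalResult]:
    """One proposal per feasible selected variant, sorted by total score.

    Infeasible variants are reported with the reason instead of being
    silently dropped.  Deterministic under a fixed configuration.
    """
    ctx = build_defect_context(warped, plan, config)
    results: list[ProposalResult] = []
    chain_cache: dict[int, SegmentChain] = {}
    for variant in variants:
        try:
            # the optimal knot placement depends only on the segment count
            if variant.n_segments not in chain_cache:
                chain_cache[variant.n_segments] = fit_segment_chain(
                    ctx, variant.n_segments, weights=config.weights,
                    pedicle_score=1.0)
            chain = chain_cache[variant.n_segments]
            proposal = assemble_proposal(variant, chain, ctx, warped, case,
                                         config)
            results.append(ProposalResult(variant.variant_id, proposal=proposal))
        except (InfeasibleChainError, HarvestLengthError,
                DegenerateGeometryError) as exc:
            results.append(ProposalResult(variant.variant_id, error=str(exc)))
    with_p = [r for r in results if r.proposal is not None]
    without = [r for r in results if r.proposal is None]
    with_p.sort(key=lambda r: (-r.proposal.score.total, r.variant_id))
    return with_p + without
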