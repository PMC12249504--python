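"""Manual-refinement operators on reconstruction proposals.

The four interactive manipulation concepts -- editing segment junctions,
adjusting the transplant level, rotating the transplant about its mid-axis
and re-positioning the resection cut planes -- are exposed as pure
functions: each returns a new, re-validated proposal and never mutates its
input.  At the junctions with the residual mandible only displacements on
the planned cut edge are permitted (off-plane components are discarded),
preserving a seamless connection.  Segments at or below the alert
threshold produce warnings, never hard failures.

Actions can be recorded in an append-only journal and replayed, which
reproduces the refined proposal exactly.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pydantic
import yaml

from .errors import InfeasibleChainError, MandrecError
from .geometry import rotation_about_axis, unit
from .proposal_engine import (DefectContext, Proposal, SegmentChain,
                              apply_level, build_defect_context,
                              check_short_segments, compute_osteotomy_planes,
                              fit_segment_chain, level_offset_mm,
                              orient_segments, plan_harvest, _score_placement,
                              score_proposal)
from .resection import build_plan, move_cut, rotate_cut


class RefinementAction(pydantic.BaseModel):
    """One recorded manual-refinement step."""

    model_config = pydantic.ConfigDict(extra="forbid")

    kind: Literal["move_junction", "adjust_level", "rotate_transplant",
                  "move_cut_plane"]
    junction_index: Optional[int] = None
    target: Optional[list[float]] = None
    level: Optional[Union[str, float]] = None
    angle_deg: float = 0.0
    cut_index: Optional[int] = None
    delta_s: float = 0.0
    reoptimize: bool = False


# --------------------------------------------------------------------------
# rebuild helper
# --------------------------------------------------------------------------

def _rebuild(proposal: Proposal, chain: SegmentChain,
             ctx: Optional[DefectContext] = None) -> Proposal:
    """Recompute osteotomies, harvest, orientation, warnings and score."""
    ctx = ctx or proposal.context
    config = ctx.config
    fibula = ctx.case.fibulae[proposal.variant.donor]
    harvest = plan_harvest(chain, fibula, proposal.variant.donor,
                           proposal.variant.pedicle_side, kerf=config.kerf)
    rolls, lat_dirs, orient_warnings = orient_segments(chain, fibula, harvest, ctx)
    chain = replace(chain.copy(), roll_angles=rolls, lateral_dirs=lat_dirs)
    osteotomies = compute_osteotomy_planes(chain, ctx.end_planes)
    warnings = list(orient_warnings)
    warnings += check_short_segments(chain, config.short_segment_threshold)
    out = Proposal(variant=proposal.variant, chain=chain,
                   osteotomies=osteotomies, harvest=harvest, score=None,
                   warnings=warnings, context=ctx)
    out.score = score_proposal(out, ctx.warped)
    return out


# --------------------------------------------------------------------------
# the four operators
# --------------------------------------------------------------------------

def move_junction(proposal: Proposal, junction_index: int,
                  target: np.ndarray) -> Proposal:
    """Displace one segment junction; terminals stay on their cut plane.

    For the two terminal junctions the target is projected onto the
    corresponding resection cut plane (only in-plane displacement is
    permitted); interior junctions move freely.  Downstream geometry and
    scores are recomputed.  A displacement collapsing a segment to zero or
    negative length is rejected; short-but-positive segments only warn.
    """
    ctx = proposal.context
    chain = proposal.chain
    n = len(chain.knots)
    if not 0 <= junction_index < n:
        raise MandrecError(f"junction index {junction_index} out of range 0..{n - 1}")
    target = np.asarray(target, float).reshape(3)
    new = chain.copy()
    if junction_index == 0:
        target = ctx.end_planes[0].project(target)
    elif junction_index == n - 1:
        target = ctx.end_planes[1].project(target)
    new.knots[junction_index] = target
    s_proj, _ = ctx.midline.project_point(target)
    new.knots_s[junction_index] = s_proj
    if np.any(new.segment_lengths < 1e-9):
        raise InfeasibleChainError(
            "displacement collapses a segment to zero length")
    if np.any(np.diff(new.knots_s) < 0):
        new.knots_s = np.sort(new.knots_s)  # keep sample assignment monotone
    return _rebuild(proposal, new)


def adjust_level(proposal: Proposal, level: Union[str, float]) -> Proposal:
    """Set the transplant level by name (basal/middle/apical) or offset (mm)."""
    ctx = proposal.context
    if isinstance(level, str):
        fibula = ctx.case.fibulae[proposal.variant.donor]
        offset = level_offset_mm(level, ctx.warped.apical_offset,
                                 fibula.diameter)
    else:
        offset = float(level)
    new = apply_level(proposal.chain, offset, ctx)
    return _rebuild(proposal, new)


def rotate_transplant(proposal: Proposal, angle_deg: float) -> Proposal:
    """Rotate the transplant rigidly about its mid-axis.

    The mid-axis runs through the two terminal knots, which stay fixed;
    interior knots and lateral-face directions rotate with the transplant,
    so all segment lengths are preserved exactly.
    """
    chain = proposal.chain
    a, b = chain.knots[0], chain.knots[-1]
    axis = unit(b - a)
    R = rotation_about_axis(axis, angle_deg)
    new = chain.copy()
    for k in range(1, len(new.knots) - 1):
        new.knots[k] = a + R @ (new.knots[k] - a)
    new.lateral_dirs = (R @ new.lateral_dirs.T).T
    return _rebuild(proposal, new)


def move_cut_plane_and_recompute(proposal: Proposal, cut_index: int,
                                 delta_s: float = 0.0, angle_deg: float = 0.0,
                                 reoptimize: bool = False) -> Proposal:
    """Re-position/re-orient a resection cut and update the proposal.

    The resection plan is rebuilt (defect re-classified, meshes re-cut) and
    the chain endpoints are re-projected onto the new cut planes.  By
    default the interior knots are preserved; with ``reoptimize`` the
    engine re-runs the knot search and returns whichever of the re-fit and
    the preserved (warm-start) chain scores higher.
    """
    ctx = proposal.context
    if ctx.plan is None or ctx.case is None:
        raise MandrecError("proposal context lacks the resection plan")
    plan = ctx.plan
    if not 0 <= cut_index < len(plan.cuts):
        raise MandrecError(f"cut index {cut_index} out of range")
    cuts = list(plan.cuts)
    cut = cuts[cut_index]
    if delta_s:
        cut = move_cut(cut, delta_s, ctx.midline)
    if angle_deg:
        cut = rotate_cut(cut, "in-plane-1", angle_deg, ctx.midline)
    cuts[cut_index] = cut
    new_plan = build_plan(ctx.case.mandible.mesh, ctx.midline,
                          ctx.warped.zone_boundaries, cuts,
                          plan.resected_side)
    new_ctx = build_defect_context(ctx.warped, new_plan, ctx.config)
    new_ctx.warped, new_ctx.case = ctx.warped, ctx.case

    interior_s = proposal.chain.knots_s[1:-1]
    interior_s = np.clip(interior_s, new_ctx.s_lo + 1e-9, new_ctx.s_hi - 1e-9)
    from .proposal_engine import _chain_from_s
    preserved = _chain_from_s(new_ctx, np.sort(interior_s))
    preserved.level_offset = proposal.chain.level_offset

    chain = preserved
    if reoptimize:
        refit = fit_segment_chain(new_ctx, proposal.chain.n_segments,
                                  weights=ctx.config.weights)
        score_refit = _score_placement(new_ctx, refit.knots_s[1:-1],
                                       ctx.config.weights, 1.0)
        score_warm = _score_placement(new_ctx, preserved.knots_s[1:-1],
                                      ctx.config.weights, 1.0)
        if score_refit >= score_warm:
            chain = refit
            chain.level_offset = proposal.chain.level_offset
    return _rebuild(proposal, chain, ctx=new_ctx)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate(proposal: Proposal, tol_mm: float = 1e-6,
             tol_rad: float = 1e-9) -> dict:
    """Re-run all proposal invariants; pure and idempotent.

    Returns ``{"violations": [...], "warnings": [...]}``; warnings (short
    segments, orientation compromises) are informational, violations mean
    the geometry breaks a contract.
    """
    ctx = proposal.context
    chain = proposal.chain
    violations: list[str] = []

    d0 = abs(float(ctx.end_planes[0].signed_distance(chain.knots[0])))
    d1 = abs(float(ctx.end_planes[1].signed_distance(chain.knots[-1])))
    if d0 > tol_mm:
        violations.append(f"first knot off cut plane by {d0:.2e} mm")
    if d1 > tol_mm:
        violations.append(f"last knot off cut plane by {d1:.2e} mm")

    axes = chain.segment_axes
    inter = [p for p in proposal.osteotomies if p.kind == "inter_segment"]
    if len(inter) != chain.n_segments - 1:
        violations.append("osteotomy plane count inconsistent with segments")
    for j, p in enumerate(inter):
        a1 = np.arccos(np.clip(p.normal @ axes[j], -1.0, 1.0))
        a2 = np.arccos(np.clip(p.normal @ axes[j + 1], -1.0, 1.0))
        if abs(a1 - a2) > tol_rad:
            violations.append(
                f"miter asymmetry at junction {j + 1}: {abs(a1 - a2):.2e} rad")
        if np.linalg.norm(p.anchor - chain.knots[j + 1]) > tol_mm:
            violations.append(f"miter plane {j + 1} not anchored at its knot")

    iv = proposal.harvest.intervals
    for (a1_, b1_), (a2_, b2_) in zip(iv[:-1], iv[1:]):
        if a2_ < b1_ - 1e-9:
            violations.append("harvest intervals overlap")
    lengths = chain.segment_lengths
    for (a_, b_), seg in zip(iv, proposal.harvest.segment_order):
        if abs((b_ - a_) - lengths[seg]) > 1e-6:
            violations.append(f"harvest interval mismatch for segment {seg + 1}")
    fib = ctx.case.fibulae[proposal.variant.donor] if ctx.case else None
    if fib is not None and iv and iv[-1][1] > fib.harvestable_length + 1e-6:
        violations.append("harvest exceeds donor fibula length")

    warnings = check_short_segments(chain, ctx.config.short_segment_threshold)
    return {"violations": violations, "warnings": warnings}


# --------------------------------------------------------------------------
# journal
# --------------------------------------------------------------------------

def apply_action(proposal: Proposal, action: RefinementAction) -> Proposal:
    if action.kind == "move_junction":
        return move_junction(proposal, action.junction_index,
                             np.asarray(action.target, float))
    if action.kind == "adjust_level":
        return adjust_level(proposal, action.level)
    if action.kind == "rotate_transplant":
        return rotate_transplant(proposal, action.angle_deg)
    if action.kind == "move_cut_plane":
        return move_cut_plane_and_recompute(
            proposal, action.cut_index, action.delta_s, action.angle_deg,
            action.reoptimize)
    raise MandrecError(f"unknown action kind {action.kind}")  # pragma: no cover


def replay(proposal: Proposal, actions: list[RefinementAction]) -> Proposal:
    """Apply a recorded action journal in order (undo = replay a prefix)."""
    out = proposal
    for action in actions:
        out = apply_action(out, action)
    return out


def read_actions(path: str | Path) -> list[RefinementAction]:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise MandrecError("actions file must be a YAML list")
    return [RefinementAction(**item) for item in raw]


def write_actions(actions: list[RefinementAction], path: str | Path) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(yaml.safe_dump(
        [a.model_dump(exclude_none=True) for a in actions], sort_keys=False))
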