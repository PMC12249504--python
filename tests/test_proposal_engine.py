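"""Chain optimizer, osteotomies, harvest, orientation, level and scoring."""

import itertools

import numpy as np
import pytest

from mandrec.errors import HarvestLengthError, InfeasibleChainError
from mandrec.geometry import Plane, rotation_about_axis, unit
from mandrec.io_formats import EngineConfig
from mandrec.registration import register_reference
from mandrec.resection import build_plan, snap_cut_to_midline
from mandrec.synthetic_anatomy import (DefectScenario, FibulaSpec,
                                       MandibleSpec, generate_case,
                                       generate_fibula)
from mandrec.variant_catalog import ReconstructionVariant
import mandrec.proposal_engine as pe


def make_context(reference, case, step=0.5, **config_kw):
    warped, _ = register_reference(reference, case.landmarks)
    cuts = [snap_cut_to_midline(p.anchor, warped.midline)
            for p in case.ground_truth.planes]
    plan = build_plan(case.mandible.mesh, warped.midline,
                      warped.zone_boundaries, cuts,
                      case.ground_truth.resected_side)
    cfg = EngineConfig(midline_step=step, **config_kw)
    ctx = pe.build_defect_context(warped, plan, cfg)
    ctx.case = case
    return ctx, warped, plan, cfg


def brute_force_best(ctx, n_segments, weights):
    """Oracle: naive nested enumeration of all interior-knot placements."""
    K = len(ctx.samples_s)
    best, best_combo = -np.inf, None
    for combo in itertools.combinations(range(1, K - 1), n_segments - 1):
        val = pe._score_placement(ctx, ctx.samples_s[list(combo)],
                                  weights, 1.0)
        if val > best:
            best, best_combo = val, combo
    return best, best_combo


class TestFitSegmentChain:
    def test_single_segment_is_chord(self, reference, lc_case):
        ctx, *_ = make_context(reference, lc_case)
        chain = pe.fit_segment_chain(ctx, 1, refine=False)
        assert chain.n_segments == 1
        chord = np.linalg.norm(chain.knots[1] - chain.knots[0])
        assert chain.segment_lengths[0] == pytest.approx(chord)

    def test_endpoints_on_cut_planes(self, reference, lc_case):
        ctx, *_ = make_context(reference, lc_case)
        for n in (1, 2, 3):
            chain = pe.fit_segment_chain(ctx, n, refine=False)
            assert abs(ctx.end_planes[0].signed_distance(chain.knots[0])) < 1e-6
            assert abs(ctx.end_planes[1].signed_distance(chain.knots[-1])) < 1e-6

    @pytest.mark.parametrize("n_segments", [2, 3])
    def test_optimizer_equals_bruteforce_on_coarse_grid(self, reference,
                                                        lc_case, n_segments):
        ctx, _, _, cfg = make_context(reference, lc_case, step=5.0)
        chain = pe.fit_segment_chain(ctx, n_segments, refine=False)
        total = pe._score_placement(ctx, chain.knots_s[1:-1], cfg.weights, 1.0)
        oracle, _ = brute_force_best(ctx, n_segments, cfg.weights)
        assert total == oracle

    def test_refinement_never_worse_than_grid(self, reference, lc_case):
        ctx, _, _, cfg = make_context(reference, lc_case, step=5.0)
        grid = pe.fit_segment_chain(ctx, 2, refine=False)
        refined = pe.fit_segment_chain(ctx, 2, refine=True)
        s_grid = pe._score_placement(ctx, grid.knots_s[1:-1], cfg.weights, 1.0)
        s_ref = pe._score_placement(ctx, refined.knots_s[1:-1], cfg.weights, 1.0)
        assert s_ref >= s_grid

    def test_min_segment_length_respected(self, reference, lc_case):
        ctx, *_ = make_context(reference, lc_case,
                               min_segment_length=12.0)
        chain = pe.fit_segment_chain(ctx, 2, refine=False)
        assert np.all(chain.segment_lengths >= 12.0)

    def test_infeasible_count_raises(self, reference, lc_case):
        ctx, *_ = make_context(reference, lc_case)
        with pytest.raises(InfeasibleChainError, match="exceed"):
            pe.fit_segment_chain(ctx, 20)
        # within the segment cap but violating the minimum length
        ctx2, *_ = make_context(reference, lc_case, min_segment_length=15.0)
        with pytest.raises(InfeasibleChainError, match="min segment length"):
            pe.fit_segment_chain(ctx2, 3)


class TestOsteotomyPlanes:
    def chain_from(self, knots):
        knots = np.asarray(knots, float)
        return pe.SegmentChain(knots=knots,
                               knots_s=np.arange(len(knots), dtype=float))

    END = (Plane([0, 0, 0], [1, 0, 0]), Plane([100, 0, 0], [1, 0, 0]))

    def test_collinear_limit_is_common_axis(self):
        chain = self.chain_from([[0, 0, 0], [50, 0, 0], [100, 0, 0]])
        planes = pe.compute_osteotomy_planes(chain, self.END)
        np.testing.assert_allclose(planes[1].normal, [1, 0, 0], atol=1e-12)

    def test_right_angle_bend_bisected_at_45deg(self):
        chain = self.chain_from([[0, 0, 0], [50, 0, 0], [50, 50, 0]])
        planes = pe.compute_osteotomy_planes(
            chain, (Plane([0, 0, 0], [1, 0, 0]), Plane([50, 50, 0], [0, 1, 0])))
        n = planes[1].normal
        a1 = np.arccos(np.clip(n @ [1, 0, 0], -1, 1))
        a2 = np.arccos(np.clip(n @ [0, 1, 0], -1, 1))
        assert abs(np.degrees(a1) - 45) < 1e-9
        assert abs(a1 - a2) < 1e-9

    def test_miter_symmetry_random_chains(self, rng):
        for _ in range(100):
            n = rng.integers(2, 5)
            knots = np.cumsum(rng.normal(0, 10, (n + 1, 3)), axis=0)
            chain = self.chain_from(knots)
            if np.any(chain.segment_lengths < 1e-6):
                continue
            end = (Plane(knots[0], chain.segment_axes[0]),
                   Plane(knots[-1], chain.segment_axes[-1]))
            axes = chain.segment_axes
            for j, p in enumerate(pe.compute_osteotomy_planes(chain, end)[1:-1]):
                a1 = np.arccos(np.clip(p.normal @ axes[j], -1, 1))
                a2 = np.arccos(np.clip(p.normal @ axes[j + 1], -1, 1))
                assert abs(a1 - a2) < 1e-9

    def test_antiparallel_segments_rejected(self):
        chain = self.chain_from([[0, 0, 0], [50, 0, 0], [0, 0, 0]])
        with pytest.raises(Exception, match="anti-parallel"):
            pe.compute_osteotomy_planes(chain, self.END)

    def test_terminal_planes_coincide_with_resection(self, lc_proposal):
        ends = lc_proposal.context.end_planes
        planes = lc_proposal.osteotomies
        np.testing.assert_allclose(planes[0].anchor, ends[0].anchor)
        np.testing.assert_allclose(planes[-1].anchor, ends[1].anchor)
        assert planes[0].kind == "junction_to_mandible"


class TestHarvest:
    def chain_with_lengths(self, lengths):
        knots = np.zeros((len(lengths) + 1, 3))
        knots[1:, 0] = np.cumsum(lengths)
        return pe.SegmentChain(knots=knots,
                               knots_s=np.arange(len(knots), dtype=float))

    def test_interval_arithmetic(self):
        fib = generate_fibula(FibulaSpec(length=240))
        chain = self.chain_with_lengths([30.0, 25.0, 20.0])
        h = pe.plan_harvest(chain, fib, "left_fibula", "right", kerf=1.0)
        assert h.intervals == [(0.0, 30.0), (31.0, 56.0), (57.0, 77.0)]
        assert h.segment_order == [0, 1, 2]

    def test_shortfall_error_in_mm(self):
        fib = generate_fibula(FibulaSpec(length=130, diameter=12))
        fib.harvestable_length = 60.0  # only part released for harvest
        chain = self.chain_with_lengths([30.0, 25.0, 20.0])
        with pytest.raises(HarvestLengthError) as err:
            pe.plan_harvest(chain, fib, "left_fibula", "right", kerf=1.0)
        assert err.value.shortfall_mm == pytest.approx(17.0)

    def test_pedicle_side_reverses_mapping(self):
        # oracle: the vessel end (interval starting at 0) must map to the
        # chain end adjacent to the anastomosis side; chain runs right->left
        fib = generate_fibula(FibulaSpec(length=240))
        chain = self.chain_with_lengths([30.0, 25.0, 20.0])
        right = pe.plan_harvest(chain, fib, "left_fibula", "right")
        left = pe.plan_harvest(chain, fib, "left_fibula", "left")
        assert right.segment_order[0] == 0      # right end of the chain
        assert left.segment_order[0] == 2       # left end of the chain
        assert left.segment_order == right.segment_order[::-1]

    def test_conservation_and_disjointness(self, rng):
        fib = generate_fibula(FibulaSpec(length=240))
        for _ in range(20):
            lengths = rng.uniform(15, 40, rng.integers(1, 5))
            chain = self.chain_with_lengths(lengths)
            h = pe.plan_harvest(chain, fib, "left_fibula",
                                rng.choice(["left", "right"]), kerf=1.0)
            ivals = np.array(h.intervals)
            assert np.all(np.diff(ivals[:, 0]) > 0)
            assert np.all(ivals[1:, 0] >= ivals[:-1, 1] + 1.0 - 1e-9)
            total = (ivals[:, 1] - ivals[:, 0]).sum()
            assert total == pytest.approx(lengths.sum())


class TestOrientation:
    def test_roll_maximizes_outward_component(self, lc_proposal):
        # brute-force oracle: no roll on a 1 degree grid beats the chosen one
        chain = lc_proposal.chain
        ctx = lc_proposal.context
        axes = chain.segment_axes
        mids = 0.5 * (chain.knots[:-1] + chain.knots[1:])
        for j in range(chain.n_segments):
            u = axes[j]
            target = pe._projected_outward(u, mids[j], ctx.outward_center)
            chosen = float(chain.lateral_dirs[j] @ target)
            ref0 = pe.perpendicular_vector(u)
            for angle in range(0, 360, 1):
                cand = rotation_about_axis(u, angle) @ ref0
                assert chosen >= float(cand @ target) - 1e-9

    def test_vessel_runs_medial(self, lc_proposal):
        chain = lc_proposal.chain
        ctx = lc_proposal.context
        mids = 0.5 * (chain.knots[:-1] + chain.knots[1:])
        for j in range(chain.n_segments):
            target = pe._projected_outward(chain.segment_axes[j], mids[j],
                                           ctx.outward_center)
            vessel_dir = -chain.lateral_dirs[j]  # generator: vessel opposite
            assert vessel_dir @ target < 1e-6


class TestLevel:
    def test_named_offsets_arithmetic(self):
        # body height 25, fibula diameter 12
        assert pe.level_offset_mm("basal", 25.0, 12.0) == 0.0
        assert pe.level_offset_mm("middle", 25.0, 12.0) == pytest.approx(6.5)
        assert pe.level_offset_mm("apical", 25.0, 12.0) == pytest.approx(13.0)

    def test_basal_is_identity(self, lc_proposal):
        ctx = lc_proposal.context
        chain = pe.apply_level(lc_proposal.chain, 0.0, ctx)
        np.testing.assert_allclose(chain.knots, lc_proposal.chain.knots)

    def test_middle_then_basal_restores(self, lc_proposal):
        ctx = lc_proposal.context
        up = pe.apply_level(lc_proposal.chain, 6.5, ctx)
        back = pe.apply_level(up, 0.0, ctx)
        assert np.abs(back.knots - lc_proposal.chain.knots).max() < 1e-9

    def test_terminals_stay_on_planes(self, lc_proposal):
        ctx = lc_proposal.context
        up = pe.apply_level(lc_proposal.chain, 10.0, ctx)
        assert abs(ctx.end_planes[0].signed_distance(up.knots[0])) < 1e-6
        assert abs(ctx.end_planes[1].signed_distance(up.knots[-1])) < 1e-6


class TestScoring:
    def test_chain_on_midline_has_unit_fidelity(self, reference, lc_case):
        ctx, *_ = make_context(reference, lc_case, step=2.0)
        # a dense chain lying on the midline samples
        idx = np.arange(0, len(ctx.samples_s))
        chain = pe.SegmentChain(knots=ctx.ref_pts[idx].copy(),
                                knots_s=ctx.samples_s[idx].copy())
        s_m, _, _ = pe.chain_component_scores(chain, ctx)
        assert s_m > 0.999

    def test_perturbation_decreases_fidelity(self, reference, lc_case):
        ctx, *_ = make_context(reference, lc_case)
        chain = pe.fit_segment_chain(ctx, 2, refine=False)
        s_m0, _, _ = pe.chain_component_scores(chain, ctx)
        moved = chain.copy()
        moved.knots[1] = moved.knots[1] + np.array([0.0, 0.0, 5.0])
        s_m1, _, _ = pe.chain_component_scores(moved, ctx)
        assert s_m1 < s_m0

    def test_weighting_changes_total_unless_components_equal(self):
        comps = {"midline_fidelity": 0.9, "symmetry": 0.8,
                 "surface_continuity": 0.7, "pedicle_feasibility": 1.0}
        balanced = pe.combine_scores(comps, {k: 1.0 for k in comps})
        doubled = pe.combine_scores(comps, {**{k: 1.0 for k in comps},
                                            "symmetry": 2.0})
        assert balanced != doubled

    def test_total_invariant_under_uniform_rescaling(self):
        comps = {"midline_fidelity": 0.9, "symmetry": 0.8,
                 "surface_continuity": 0.7, "pedicle_feasibility": 1.0}
        w1 = {k: 1.0 for k in comps}
        w3 = {k: 3.0 for k in comps}
        assert pe.combine_scores(comps, w1) == pytest.approx(
            pe.combine_scores(comps, w3))

    def test_disabled_criteria_excluded_from_normalization(self):
        comps = {"midline_fidelity": 0.5, "symmetry": 1.0,
                 "surface_continuity": 0.0, "pedicle_feasibility": 0.0}
        w = {"midline_fidelity": 1.0, "symmetry": 1.0,
             "surface_continuity": 0.0, "pedicle_feasibility": 0.0}
        assert pe.combine_scores(comps, w) == pytest.approx(0.75)


class TestShortSegments:
    def chain_with_lengths(self, lengths):
        knots = np.zeros((len(lengths) + 1, 3))
        knots[1:, 0] = np.cumsum(lengths)
        return pe.SegmentChain(knots=knots,
                               knots_s=np.arange(len(knots), dtype=float))

    def test_alert_at_and_below_threshold(self):
        warn = pe.check_short_segments(self.chain_with_lengths([30.0, 2.4]))
        assert len(warn) == 1 and "segment 2" in warn[0]
        assert pe.check_short_segments(self.chain_with_lengths([30.0, 2.6])) == []
        assert len(pe.check_short_segments(self.chain_with_lengths([2.5]))) == 1


class TestCalculateProposals:
    def test_counts_and_plane_count(self, lc_proposal):
        assert lc_proposal.chain.n_segments == 2
        assert len(lc_proposal.osteotomies) == 3

    def test_every_selected_variant_gets_a_record(self, lc_case,
                                                  lc_registered, lc_plan):
        warped, _ = lc_registered
        variants = [ReconstructionVariant(n, d, p, "none")
                    for n, d, p in [(1, "left_fibula", "left"),
                                    (2, "right_fibula", "right"),
                                    (2, "left_fibula", "left"),
                                    (12, "left_fibula", "left")]]
        results = pe.calculate_proposals(lc_plan, variants, warped, lc_case,
                                         EngineConfig())
        assert len(results) == 4
        infeasible = [r for r in results if r.proposal is None]
        assert len(infeasible) == 1 and "exceed" in infeasible[0].error

    def test_deterministic_report(self, lc_case, lc_registered, lc_plan):
        import json
        warped, _ = lc_registered
        variants = [ReconstructionVariant(2, "left_fibula", "left", "none")]
        a = pe.calculate_proposals(lc_plan, variants, warped, lc_case,
                                   EngineConfig())
        b = pe.calculate_proposals(lc_plan, variants, warped, lc_case,
                                   EngineConfig())
        assert json.dumps([r.to_dict() for r in a], sort_keys=True) == \
            json.dumps([r.to_dict() for r in b], sort_keys=True)

    def test_sorted_by_total_score(self, lc_case, lc_registered, lc_plan):
        warped, _ = lc_registered
        variants = [ReconstructionVariant(n, "left_fibula", "left", "none")
                    for n in (1, 2)]
        results = pe.calculate_proposals(lc_plan, variants, warped, lc_case,
                                         EngineConfig())
        totals = [r.proposal.score.total for r in results if r.proposal]
        assert totals == sorted(totals, reverse=True)


def test_segment_mesh_export(lc_proposal, lc_case):
    fib = lc_case.fibulae[lc_proposal.variant.donor]
    meshes = pe.export_segment_meshes(lc_proposal, fib)
    assert len(meshes) == lc_proposal.chain.n_segments
    for m, L in zip(meshes, lc_proposal.chain.segment_lengths):
        assert m.is_watertight
        # roughly a cylinder of the fibula diameter and the segment length
        expected = np.pi * (fib.diameter / 2) ** 2 * L
        assert m.volume == pytest.approx(expected, rel=0.35)
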