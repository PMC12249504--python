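# mandrec

Knowledge-based virtual surgical planning (VSP) for tumor-related
mandibular reconstruction with free fibula flaps, as a headless Python
library and CLI.

## The problem

After segmental resection of the mandible (for tumors), the standard
reconstruction bridges the defect with one or more vascularized bone
segments harvested from the patient's fibula. Planning such a
reconstruction means deciding, on 3D models of the patient's bones, where
the resection cuts go, how many straight fibula segments to use, where
each osteotomy plane lies so adjacent segments mate seamlessly (miter
joints), which leg to harvest from, where the vascular pedicle must reach
for anastomosis, and how the segments are oriented and positioned to
restore a natural mandibular shape. `mandrec` implements this pipeline for
surgeons' workflows that start from segmented surface meshes:

1. **Reference registration** — a canonical mandible model carrying 14
   named anatomical landmarks (pogonion, gnathion, and the paired mental
   foramen, canine point, gonion, antegonial notch, coronoid tip and
   condylion sites), the mandibular midline, HCL zone boundaries and
   lateral-face markings is fitted to the patient's mandible by an
   interpolating 3D thin-plate spline on at least six corresponding
   landmarks. Landmarks that cannot be placed may be skipped; for
   unilateral defects the healthy side can be mirrored across the
   estimated median plane.
2. **Resection planning** — one or two planar cuts are snapped onto the
   nearest point of the registered midline, oriented perpendicular to the
   local bone axis, and may be moved/rotated. The mandible mesh is
   partitioned into resected and residual parts (closed along the cut
   faces) and the defect is classified in Jewer HCL terms (C = canine to
   canine, L = lateral body, H = lateral including the condyle; classes
   concatenate, e.g. LC, LCL, HCL).
3. **Variant enumeration and automatic proposals** — a declarative
   knowledge base enumerates every reconstruction variant (segment count x
   donor fibula x pedicle side x skin-island orientation) able to bridge
   the defect. For each selected variant the engine places the segment
   chain on the warped reference midline by an exact search over knot
   placements, maximizing a weighted score with four criteria in [0, 1]:

   - midline fidelity  `s_m = exp(-d̄_mid / τ_m)`
   - symmetry          `s_s = exp(-d̄_sym / τ_s)`
   - lateral-surface continuity (mean junction cosine)
   - pedicle feasibility (reach to the anastomosis site)

   with `total = Σ wᵢ sᵢ / Σ wᵢ`; the default weighting is balanced. The
   engine then derives miter osteotomy planes (bisectors of adjacent
   segment axes), maps segments to disjoint harvest intervals on the donor
   fibula (pedicle-proximal first, order reversed when the anastomosis
   side requires it), rolls each segment so the fibula's lateral face
   points outward while the vessels run medially, and applies the chosen
   transplant level (basal / middle / apical).
4. **Manual refinement** — pure, scriptable operators: junction editing
   (terminal junctions may only slide on the planned cut edge), a level
   slider, rotation of the transplant about its mid-axis, and cut-plane
   re-positioning with re-classification. Segments ≤ 2.5 mm trigger
   warnings, never hard failures. Actions are journaled and replayable.

Patient datasets for this task are generally not shareable, so the
package ships a deterministic synthetic-anatomy generator (parametric
mandible + fibula + defect scenarios with ground truth) that makes the
whole pipeline testable end to end.

## Worked example

```sh
mandrec run --class LC --seed 3 --out case_dir/
```

prints

```
case written to case_dir (LC/left)
registered: max landmark residual 1.60e-14 mm, mean surface distance 0.03 mm
defect classified as LC (35.0 mm)
8/8 proposals written to case_dir/proposals/report.json
  2seg-left_fibula-ped_left-skin_none: total 0.883
  2seg-left_fibula-ped_right-skin_none: total 0.883
  2seg-right_fibula-ped_left-skin_none: total 0.883
  2seg-right_fibula-ped_right-skin_none: total 0.883
  1seg-left_fibula-ped_left-skin_none: total 0.761
  1seg-left_fibula-ped_right-skin_none: total 0.761
  1seg-right_fibula-ped_right-skin_none: total 0.761
  1seg-right_fibula-ped_left-skin_none: total 0.761
```

Reading the output: the synthetic case has a 35 mm left-sided defect
crossing the canine boundary (class LC). The thin-plate spline matches
all 14 landmark pairs to numerical round-off (1.6e-14 mm), and the warped
reference surface sits 0.03 mm from the patient surface on average (the
patient here is a re-generated instance of the same parametric family).
Eight variants can bridge 35 mm (1 or 2 segments, two donors, two pedicle
sides); the two-segment chains follow the curved midline more closely
than the single-segment chord, hence their higher total score (0.883 vs
0.761). The report JSON contains, per proposal, the variant descriptor,
segment lengths, osteotomy plane equations, harvest intervals, the score
breakdown and any warnings.

The same workflow is available step by step (`mandrec generate`,
`register`, `resect`, `variants`, `plan`, `refine`, `vessel`) and as a
library (see `mandrec.proposal_engine.calculate_proposals`).

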