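"""Knowledge base of reconstruction variants bridging a mandibular defect.

Variants differ along four discrete axes: number of fibula segments, donor
side, recipient-side vascular pedicle location, and orientation of an
optional skin island.  The inventory is declarative (``data/variants.yaml``)
so the knowledge can evolve without touching the algorithms; enumeration is
the cross product of the axes restricted by segment-count bounds derived
from the defect arc length and by feasibility predicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .io_formats import EngineConfig
from .resection import ResectionPlan

_SKIN_ISLAND_ORDER = {"none": 0, "lateral": 1, "medial": 2}


@dataclass(frozen=True)
class ReconstructionVariant:
    """Discrete descriptor of one way to bridge the defect."""

    n_segments: int
    donor: str            # left_fibula | right_fibula
    pedicle_side: str     # recipient anastomosis side: left | right
    skin_island: str      # none | lateral | medial

    @property
    def variant_id(self) -> str:
        return (f"{self.n_segments}seg-{self.donor}"
                f"-ped_{self.pedicle_side}-skin_{self.skin_island}")

    def sort_key(self):
        return (self.n_segments, self.donor, self.pedicle_side,
                _SKIN_ISLAND_ORDER[self.skin_island])


@dataclass(frozen=True)
class VariantQuery:
    donor_filter: Optional[str] = None
    pedicle_filter: Optional[str] = None
    skin_island_filter: Optional[str] = None


def load_knowledge(path: str | Path | None = None) -> dict:
    """Load the variant knowledge file (packaged default or explicit path)."""
    if path is None:
        text = (resources.files("mandrec") / "data" / "variants.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data.get("schema_version") != 1:
        raise ValueError("unsupported variants.yaml schema_version")
    return data


def _segment_count_range(defect_arc: float, max_seg: float, min_practical: float,
                         max_segments: int) -> list[int]:
    if defect_arc > max_segments * max_seg:
        return []
    n_lo = max(1, math.ceil(defect_arc / max_seg))
    n_hi = min(max_segments, max(n_lo, math.floor(defect_arc / min_practical)))
    return list(range(n_lo, n_hi + 1))


def _skin_island_feasible(island: str, rules: list[str]) -> bool:
    if "skin_island_not_medial" in rules and island == "medial":
        return False
    return True


def enumerate_variants(plan: ResectionPlan, config: EngineConfig,
                       knowledge: dict | None = None) -> list[ReconstructionVariant]:
    """All variants able to bridge the classified defect, deterministically ordered.

    Segment counts span ``ceil(arc/max_seg_len)`` to
    ``min(max_segments, floor(arc/min_practical_len))``.  Mono-segment
    variants for defects spanning multiple zones (e.g. across the gonial
    angle) are included only when ``config.allow_mono_segment`` is set; for
    single-zone defects they are standard whenever the length bound allows.
    """
    kb = knowledge or load_knowledge()
    axes = kb["axes"]
    rules = kb.get("feasibility", [])
    defect_arc = float(plan.defect_interval[1] - plan.defect_interval[0])

    counts = _segment_count_range(defect_arc, config.max_segment_length,
                                  config.min_practical_segment_length,
                                  config.max_segments)
    if not counts:
        warnings.warn(
            f"defect arc {defect_arc:.1f} mm exceeds "
            f"{config.max_segments} x {config.max_segment_length:.0f} mm; "
            "no variant can bridge it", stacklevel=2)
        return []

    multi_zone = len(plan.hcl_class) > 1
    if multi_zone and not config.allow_mono_segment:
        counts = [n for n in counts if n > 1]

    variants = [
        ReconstructionVariant(n, donor, pedicle, island)
        for n in counts
        for donor in axes["donors"]
        for pedicle in axes["pedicle_sides"]
        for island in axes["skin_islands"]
        if _skin_island_feasible(island, rules)
    ]
    return sorted(variants, key=ReconstructionVariant.sort_key)


def filter_variants(variants: list[ReconstructionVariant],
                    query: VariantQuery) -> list[ReconstructionVariant]:
    """Conjunctive filtering along the three axes; order preserved."""
    out = variants
    if query.donor_filter is not None:
        out = [v for v in out if v.donor == query.donor_filter]
    if query.pedicle_filter is not None:
        out = [v for v in out if v.pedicle_side == query.pedicle_filter]
    if query.skin_island_filter is not None:
        out = [v for v in out if v.skin_island == query.skin_island_filter]
    return list(out)


def describe_variant(variant: ReconstructionVariant) -> str:
    """Human-readable summary: segments, donor site, pedicle location."""
    donor = variant.donor.replace("_", " ")
    island = ("no skin island" if variant.skin_island == "none"
              else f"{variant.skin_island} skin island")
    plural = "s" if variant.n_segments != 1 else ""
    return (f"{variant.n_segments} segment{plural} from the {donor}, "
            f"pedicle on the {variant.pedicle_side}, {island}")


def parse_variant_id(variant_id: str) -> ReconstructionVariant:
    """Inverse of ``ReconstructionVariant.variant_id``."""
    try:
        seg, donor, ped, skin = variant_id.split("-")
        return ReconstructionVariant(int(seg.removesuffix("seg")), donor,
                                     ped.removeprefix("ped_"),
                                     skin.removeprefix("skin_"))
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"malformed variant id '{variant_id}'") from exc
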