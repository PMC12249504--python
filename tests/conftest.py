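"""Shared fixtures: a synthetic case taken through the whole pipeline."""

import numpy as np
import pytest

from mandrec.io_formats import EngineConfig
from mandrec.registration import default_reference, register_reference
from mandrec.resection import build_plan, snap_cut_to_midline
from mandrec.synthetic_anatomy import (DefectScenario, FibulaSpec,
                                       MandibleSpec, generate_case)
from mandrec.variant_catalog import ReconstructionVariant
import mandrec.proposal_engine as pe


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def lc_case():
    return generate_case(MandibleSpec(seed=1), FibulaSpec(seed=1),
                         DefectScenario(hcl_class="LC", side="left"))


@pytest.fixture(scope="session")
def lc_registered(reference, lc_case):
    warped, tps = register_reference(reference, lc_case.landmarks)
    return warped, tps


@pytest.fixture(scope="session")
def lc_plan(lc_case, lc_registered):
    warped, _ = lc_registered
    cuts = [snap_cut_to_midline(p.anchor, warped.midline)
            for p in lc_case.ground_truth.planes]
    return build_plan(lc_case.mandible.mesh, warped.midline,
                      warped.zone_boundaries, cuts,
                      lc_case.ground_truth.resected_side)


@pytest.fixture(scope="session")
def lc_proposal(lc_case, lc_registered, lc_plan):
    warped, _ = lc_registered
    config = EngineConfig()
    variant = ReconstructionVariant(2, "left_fibula", "left", "none")
    results = pe.calculate_proposals(lc_plan, [variant], warped, lc_case,
                                     config)
    assert results[0].proposal is not None
    return results[0].proposal


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
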