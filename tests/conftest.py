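import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import grmkit as gk

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    return gk.AbilityGrid.standard_normal()


@pytest.fixture(scope="session")
def reference_scales():
    return gk.lvqol_reference_scales()


@pytest.fixture(scope="session")
def reading_recovery(reference_scales):
    """One parameter-recovery calibration: n = 1000 simulated from the
    published 7-item reading-dimension parameters, then refitted."""
    scale = reference_scales["Reading and fine work"]
    design = gk.SimulationDesign(scale=scale, n_persons=1000, seed=42)
    responses, _, truth = gk.simulate_responses(design)
    result = gk.fit_grm(responses, compute_se=False)
    return scale, responses, truth, result


@pytest.fixture(scope="session")
def dif_null_replicates(reference_scales):
    """Hierarchical DIF slope tests on 500 null replicates (no DIF, no
    impact; two groups of 500 drawn from one population; 4-item scale)."""
    scale = reference_scales["Adjustment"]
    out = []
    for rep in range(500):
        design = gk.SimulationDesign(
            scale=scale, n_persons=1000, group_fraction=0.5, seed=10_000 + rep
        )
        responses, subgroup, _ = gk.simulate_responses(design)
        fit = gk.fit_grm(responses, compute_se=False)
        recoded = gk.apply_category_maps(responses, fit.category_maps)
        result = gk.hierarchical_dif_test(recoded, subgroup, fit.scale, "item12")
        out.append(result)
    return out


@pytest.fixture(scope="session")
def sx2_null_replicates(reference_scales):
    """S-X^2 statistics for every item of a 5-item scale over 200 data sets
    simulated and refitted under the generating model (n = 500 each)."""
    scale = reference_scales["Basic aspects"]
    out = []
    for rep in range(200):
        design = gk.SimulationDesign(
            scale=scale, n_persons=500, group_fraction=0.0, seed=20_000 + rep
        )
        responses, _, _ = gk.simulate_responses(design)
        fit = gk.fit_grm(responses, compute_se=False)
        recoded = gk.apply_category_maps(responses, fit.category_maps)
        for item_id in scale.item_ids:
            out.append(gk.s_x2_item_fit(recoded, fit.scale, item_id))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
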