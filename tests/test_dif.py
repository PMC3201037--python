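"""Two-group likelihood-ratio DIF tests, expected-score DIF, removal rules."""

import numpy as np
import pytest

import grmkit as gk
from grmkit.dif import DEFAULT_ES_GRID
from grmkit.errors import ConfigurationError, InsufficientDataError


def _published_profile(item_id):
    """DIFResult objects reconstructed from the published two-group rows."""
    results = []
    for row in gk.lvqol_dif_rows():
        if row.item_id != item_id:
            continue
        es, es_max, th = gk.expected_score_dif(row.params_first, row.params_second)
        nonuniform = row.df == 1
        results.append(
            gk.DIFResult(
                item_id=row.item_id,
                variable_name=row.variable,
                g2_slope=row.g2 if nonuniform else 0.2,
                df_slope=1,
                p_slope=row.p_value if nonuniform else 0.65,
                g2_thresholds=None if nonuniform else row.g2,
                df_thresholds=None if nonuniform else row.df,
                p_thresholds=None if nonuniform else row.p_value,
                classification="non-uniform" if nonuniform else "uniform",
                es_theta=DEFAULT_ES_GRID,
                es_curve=es,
                es_delta_max=es_max,
                theta_at_max=th,
                focal_mean=0.0,
                focal_sd=1.0,
            )
        )
    return results


class TestExpectedScoreDif:
    def test_identical_parameters_give_zero_at_grid_start(self):
        row = gk.lvqol_dif_rows()[0]
        es, es_max, th = gk.expected_score_dif(row.params_first, row.params_first)
        assert es_max == 0.0
        assert th == DEFAULT_ES_GRID[0]
        assert np.all(es == 0.0)

    @pytest.mark.parametrize("row", gk.lvqol_dif_rows(),
                             ids=lambda r: f"{r.item_id}-{r.variable}")
    def test_published_magnitudes_reproduced(self, row):
        es, es_max, th = gk.expected_score_dif(row.params_first, row.params_second)
        tol = 0.02 if (row.item_id, row.variable) != ("item1", "administration") else 0.04
        assert es_max == pytest.approx(row.es_delta_max, abs=tol)
        assert th == pytest.approx(row.theta_at_max, abs=0.15)

    def test_swap_flips_sign(self):
        row = gk.lvqol_dif_rows()[-1]
        _, es_ab, _ = gk.expected_score_dif(row.params_first, row.params_second)
        _, es_ba, _ = gk.expected_score_dif(row.params_second, row.params_first)
        assert es_ab == pytest.approx(-es_ba, abs=1e-12)

    def test_category_mismatch_rejected(self):
        a = gk.ItemParameters("x", 1.0, np.array([0.0]))
        b = gk.ItemParameters("x", 1.0, np.array([0.0, 1.0]))
        with pytest.raises(gk.InvalidParameterError):
            gk.expected_score_dif(a, b)


@pytest.fixture(scope="module")
def null_two_group(reference_scales):
    scale = reference_scales["Adjustment"]
    rm, subgroup, _ = gk.simulate_responses(
        gk.SimulationDesign(scale=scale, n_persons=800, group_fraction=0.5, seed=61)
    )
    fit = gk.fit_grm(rm, compute_se=False)
    recoded = gk.apply_category_maps(rm, fit.category_maps)
    return recoded, subgroup, fit.scale


class TestFitTwoGroup:
    def test_identical_halves_agree_under_free_constraint(self, null_two_group):
        rm, subgroup, scale = null_two_group
        fit = gk.fit_two_group(rm, subgroup, scale, "item12", "free")
        a, b = fit.grouped_item.group_a, fit.grouped_item.group_b
        assert abs(a.slope - b.slope) < 1.2
        assert np.max(np.abs(a.thresholds - b.thresholds)) < 0.6

    def test_anchor_set_must_be_nonempty(self, null_two_group):
        rm, subgroup, scale = null_two_group
        single = gk.ScaleParameters("one", (scale.items[0],))
        with pytest.raises(ConfigurationError):
            gk.fit_two_group(rm.subset([scale.item_ids[0]]), subgroup, single,
                             scale.item_ids[0], "free")

    def test_group_without_observations_rejected(self, null_two_group):
        rm, subgroup, scale = null_two_group
        codes = rm.codes.copy()
        focal = subgroup.focal_mask()
        codes[focal, 0] = -1
        broken = gk.ResponseMatrix(rm.persons, rm.items, codes, rm.n_categories)
        with pytest.raises(InsufficientDataError):
            gk.fit_two_group(broken, subgroup, scale, rm.items[0], "equal")

    def test_focal_impact_recovered_without_dif(self, reference_scales):
        scale = reference_scales["Adjustment"]
        rm, subgroup, _ = gk.simulate_responses(
            gk.SimulationDesign(scale=scale, n_persons=2000, group_fraction=0.5,
                                focal_mean=0.5, seed=50_000)
        )
        fit = gk.fit_grm(rm, compute_se=False)
        recoded = gk.apply_category_maps(rm, fit.category_maps)
        two = gk.fit_two_group(recoded, subgroup, fit.scale, "item12", "equal")
        assert two.focal_mean == pytest.approx(0.5, abs=0.15)


class TestHierarchicalTest:
    def test_hierarchy_and_classification_invariants(self, null_two_group, dif_null_replicates):
        rm, subgroup, scale = null_two_group
        results = [gk.hierarchical_dif_test(rm, subgroup, scale, i) for i in scale.item_ids[:2]]
        for r in results + dif_null_replicates[:50]:
            if r.p_slope < 0.01:
                assert r.classification == "non-uniform"
                assert r.g2_thresholds is None
            else:
                assert r.g2_thresholds is not None
                # df equals the number of thresholds actually estimated
                # (5 for a full 6-category item, fewer after collapsing)
                assert r.df_thresholds == r.group_parameters.group_a.thresholds.size
                expected = "uniform" if r.p_thresholds < 0.01 else "none"
                assert r.classification == expected
            assert r.g2_slope >= 0.0
            curve_at_max = r.es_curve[np.argmin(np.abs(r.es_theta - r.theta_at_max))]
            assert curve_at_max == pytest.approx(r.es_delta_max, abs=1e-9)

    def test_label_swap_preserves_g2_and_flips_es(self, null_two_group):
        rm, subgroup, scale = null_two_group
        fwd = gk.hierarchical_dif_test(rm, subgroup, scale, "item12")
        rev = gk.hierarchical_dif_test(rm, subgroup.swapped(), scale, "item12")
        assert fwd.g2_slope == pytest.approx(rev.g2_slope, abs=0.2)
        assert fwd.es_delta_max == pytest.approx(-rev.es_delta_max, abs=0.1)

    def test_null_slope_g2_matches_chi_square_1(self, dif_null_replicates):
        g2 = np.array([r.g2_slope for r in dif_null_replicates])
        q99 = float(np.quantile(g2, 0.99))
        assert 5.0 <= q99 <= 8.5

    def test_uniform_dif_is_detected_and_classified(self, reference_scales):
        scale = reference_scales["Adjustment"]
        hits = 0
        for seed in range(6):
            rm, subgroup, _ = gk.simulate_responses(
                gk.SimulationDesign(scale=scale, n_persons=1000, group_fraction=0.5,
                                    seed=40_000 + seed,
                                    dif_edits=(gk.DifEdit("item12", "uniform", 0.5),))
            )
            fit = gk.fit_grm(rm, compute_se=False)
            recoded = gk.apply_category_maps(rm, fit.category_maps)
            r = gk.hierarchical_dif_test(recoded, subgroup, fit.scale, "item12")
            hits += r.classification == "uniform"
        assert hits >= 4

    def test_nonuniform_dif_is_detected_and_classified(self, reference_scales):
        scale = reference_scales["Adjustment"]
        hits = 0
        for seed in range(6):
            rm, subgroup, _ = gk.simulate_responses(
                gk.SimulationDesign(scale=scale, n_persons=1000, group_fraction=0.5,
                                    seed=40_000 + seed,
                                    dif_edits=(gk.DifEdit("item12", "non-uniform", 2.0),))
            )
            fit = gk.fit_grm(rm, compute_se=False)
            recoded = gk.apply_category_maps(rm, fit.category_maps)
            r = gk.hierarchical_dif_test(recoded, subgroup, fit.scale, "item12")
            hits += r.classification == "non-uniform"
        assert hits >= 4


class TestRemovalDecision:
    def test_large_expected_score_difference_removes(self):
        decision = gk.removal_decision(_published_profile("item24"))
        assert decision.remove
        assert any("ES_dmax" in reason for reason in decision.reasons)

    def test_dif_on_two_variables_removes(self):
        decision = gk.removal_decision(_published_profile("item1"))
        assert decision.remove
        assert any("2 variables" in reason for reason in decision.reasons)

    @pytest.mark.parametrize("item_id", ["item3", "item7", "item19", "item12"])
    def test_single_variable_small_es_kept(self, item_id):
        decision = gk.removal_decision(_published_profile(item_id))
        assert not decision.remove
        assert decision.reasons == []

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            gk.removal_decision([])

    def test_mixed_items_rejected(self):
        with pytest.raises(ConfigurationError):
            gk.removal_decision(_published_profile("item24") + _published_profile("item19"))
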