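"""Marginal-maximum-likelihood calibration, EAP scoring, and reliability."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import grmkit as gk
from grmkit.errors import DegenerateItemError, InsufficientDataError, SchemaError


def _make_rm(codes, n_categories=6):
    codes = np.asarray(codes)
    persons = tuple(f"p{i}" for i in range(codes.shape[0]))
    items = tuple(f"i{j}" for j in range(codes.shape[1]))
    return gk.ResponseMatrix(persons, items, codes, n_categories)


class TestResponseMatrix:
    def test_out_of_range_code_rejected(self):
        with pytest.raises(SchemaError):
            _make_rm([[0, 7]], n_categories=6)

    def test_missing_is_not_a_code(self):
        rm = _make_rm([[0, -1], [2, 3]])
        df = rm.to_dataframe()
        assert np.isnan(df.iloc[0, 1])
        assert gk.ResponseMatrix.from_dataframe(df).codes.tolist() == rm.codes.tolist()

    def test_subset_keeps_order(self):
        rm = _make_rm([[0, 1, 2]])
        sub = rm.subset(["i2", "i0"])
        assert sub.items == ("i2", "i0")
        assert sub.codes.tolist() == [[2, 0]]


class TestMarginalLogLikelihood:
    def test_single_binary_response_matches_direct_quadrature(self, grid):
        item = gk.ItemParameters("i0", 1.7, np.array([0.4]))
        scale = gk.ScaleParameters("s", (item,))
        rm = _make_rm([[1]], n_categories=2)
        ll = gk.marginal_log_likelihood(rm, scale, grid)
        oracle = np.log(np.sum(grid.weights * expit(1.7 * (grid.points - 0.4))))
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_all_missing_gives_zero(self, grid):
        item = gk.ItemParameters("i0", 1.7, np.array([0.4]))
        scale = gk.ScaleParameters("s", (item,))
        rm = _make_rm([[-1], [-1]], n_categories=2)
        assert gk.marginal_log_likelihood(rm, scale, grid) == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_persons_double_loglik(self, grid, reference_scales):
        scale = reference_scales["Adjustment"]
        rm, _, _ = gk.simulate_responses(
            gk.SimulationDesign(scale=scale, n_persons=40, seed=5)
        )
        ll1 = gk.marginal_log_likelihood(rm, scale, grid)
        doubled = gk.ResponseMatrix(
            rm.persons + tuple(p + "b" for p in rm.persons),
            rm.items,
            np.vstack([rm.codes, rm.codes]),
            rm.n_categories,
        )
        assert gk.marginal_log_likelihood(doubled, scale, grid) == pytest.approx(2 * ll1)

    def test_item_mismatch_raises(self, grid, reference_scales):
        rm = _make_rm([[0, 1]])
        with pytest.raises(SchemaError):
            gk.marginal_log_likelihood(rm, reference_scales["Adjustment"], grid)

    def test_default_grid_resolution_suffices(self, reference_scales):
        scale = reference_scales["Adjustment"]
        rm, _, _ = gk.simulate_responses(
            gk.SimulationDesign(scale=scale, n_persons=100, seed=11)
        )
        ll61 = gk.marginal_log_likelihood(rm, scale, gk.AbilityGrid.standard_normal(n=61))
        ll101 = gk.marginal_log_likelihood(rm, scale, gk.AbilityGrid.standard_normal(n=101))
        assert abs(ll61 - ll101) < 1e-4


class TestFitGrm:
    def test_em_loglik_is_monotone(self, reading_recovery):
        _, _, _, result = reading_recovery
        history = np.asarray(result.ll_history)
        assert np.all(np.diff(history) >= -1e-8)
        assert result.converged

    def test_thresholds_ordered_in_fit(self, reading_recovery):
        _, _, _, result = reading_recovery
        for item in result.scale.items:
            assert np.all(np.diff(item.thresholds) >= 0)

    def test_parameter_recovery(self, reading_recovery):
        truth_scale, _, _, result = reading_recovery
        true_a = np.array([it.slope for it in truth_scale.items])
        est_a = np.array([it.slope for it in result.scale.items])
        true_b = np.vstack([it.thresholds for it in truth_scale.items])
        est_b = np.vstack([it.thresholds for it in result.scale.items])
        assert np.sqrt(np.mean((est_a - true_a) ** 2)) <= 0.25
        assert np.sqrt(np.mean((est_b - true_b) ** 2)) <= 0.20

    def test_fitted_loglik_matches_independent_quadrature(self, reading_recovery, grid):
        _, rm, _, result = reading_recovery
        recoded = gk.apply_category_maps(rm, result.category_maps)
        direct = gk.marginal_log_likelihood(recoded, result.scale, result.grid)
        assert direct == pytest.approx(result.log_likelihood, abs=1e-6)

    def test_refit_from_solution_is_fixed_point(self, reading_recovery):
        _, rm, _, result = reading_recovery
        again = gk.fit_grm(rm, start=result.scale, compute_se=False)
        assert again.converged
        assert again.n_iterations <= 2
        assert abs(again.log_likelihood - result.log_likelihood) < 1e-5

    def test_binary_items_match_direct_optimizer(self, grid):
        # 3-item two-parameter-logistic toy set against a brute-force
        # optimizer of the same marginal likelihood
        rng = np.random.default_rng(77)
        true = [(1.2, -0.5), (1.8, 0.3), (0.9, 0.8)]
        n = 600
        theta = rng.standard_normal(n)
        codes = np.column_stack(
            [(rng.random(n) < expit(a * (theta - b))).astype(int) for a, b in true]
        )
        rm = _make_rm(codes, n_categories=2)

        def negll(x):
            ll_points = np.zeros((n, grid.points.size))
            for j in range(3):
                p = expit(np.exp(x[2 * j]) * (grid.points - x[2 * j + 1]))
                ll_points += np.where(
                    codes[:, j:j + 1] == 1, np.log(p)[None, :], np.log(1 - p)[None, :]
                )
            from scipy.special import logsumexp

            return -logsumexp(ll_points + np.log(grid.weights)[None, :], axis=1).sum()

        x0 = np.array([v for a, b in true for v in (np.log(a), b)])
        brute = minimize(negll, x0, method="Nelder-Mead",
                         options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        fit = gk.fit_grm(rm, grid, tol=1e-9, param_tol=1e-6, max_iter=3000,
                         compute_se=False)
        est = np.array([v for it in fit.scale.items
                        for v in (it.slope, it.thresholds[0])])
        ref = np.array([v for j in range(3)
                        for v in (np.exp(brute.x[2 * j]), brute.x[2 * j + 1])])
        assert np.max(np.abs(est - ref)) < 1e-3

    def test_single_category_item_rejected(self):
        rm = _make_rm([[0, 1], [0, 2], [0, 1]])
        with pytest.raises(DegenerateItemError):
            gk.fit_grm(rm, compute_se=False)

    def test_unobserved_middle_category_collapsed(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 4, size=200)
        col[col == 2] = 3  # category 2 never observed
        other = rng.integers(0, 4, size=200)
        rm = _make_rm(np.column_stack([col, other]), n_categories=4)
        result = gk.fit_grm(rm, compute_se=False)
        assert result.category_maps["i0"] == {0: 0, 1: 1, 3: 2}
        assert result.scale.item("i0").n_categories == 3

    def test_standard_errors_positive_and_shrink_with_n(self, reference_scales, grid):
        scale = reference_scales["Adjustment"]
        ses = {}
        for n in (150, 600):
            rm, _, _ = gk.simulate_responses(
                gk.SimulationDesign(scale=scale, n_persons=n, seed=8, missing_rate=0.0)
            )
            res = gk.fit_grm(rm, grid, compute_se=True)
            ses[n] = res.standard_errors
        ratios = [
            ses[600][item] / ses[150][item]
            for item in scale.item_ids
            if ses[600][item].size == ses[150][item].size
        ]
        assert ratios, "no item had the same category structure at both sizes"
        small = np.concatenate([ses[150][i] for i in ses[150]])
        assert np.all(small[np.isfinite(small)] > 0)
        assert np.nanmedian(np.concatenate(ratios)) < 0.8


class TestEapScores:
    def test_unscored_person_carries_prior(self, reference_scales, grid):
        scale = reference_scales["Adjustment"]
        codes = np.full((1, 4), -1)
        rm = gk.ResponseMatrix(("p0",), tuple(scale.item_ids), codes, 6)
        post = gk.eap_scores(rm, scale, grid)[0]
        assert post.eap_mean == pytest.approx(0.0, abs=1e-12)
        assert post.posterior_sd == pytest.approx(1.0, abs=1e-3)
        assert post.n_items_observed == 0

    def test_mirrored_pattern_gives_negated_eap(self, grid):
        # symmetric two-item scale; reversing category codes mirrors theta
        items = tuple(
            gk.ItemParameters(f"i{j}", 1.5, np.array([-1.0, -0.3, 0.3, 1.0]))
            for j in range(2)
        )
        scale = gk.ScaleParameters("sym", items)
        rm = gk.ResponseMatrix(("a", "b"), tuple(i.item_id for i in items),
                               np.array([[0, 1], [4, 3]]), 5)
        post = gk.eap_scores(rm, scale, grid)
        assert post[0].eap_mean == pytest.approx(-post[1].eap_mean, abs=1e-8)

    def test_posterior_sd_below_prior(self, reading_recovery):
        _, rm, _, result = reading_recovery
        recoded = gk.apply_category_maps(rm, result.category_maps)
        for p in gk.eap_scores(recoded, result.scale, result.grid):
            if p.n_items_observed:
                assert p.posterior_sd <= 1.0

    def test_eap_tracks_generating_theta(self, reading_recovery):
        _, rm, truth, result = reading_recovery
        recoded = gk.apply_category_maps(rm, result.category_maps)
        means = np.array([p.eap_mean for p in gk.eap_scores(recoded, result.scale, result.grid)])
        assert np.corrcoef(means, truth["theta"])[0, 1] > 0.85


class TestSubjectSeparation:
    def test_perfect_separation(self):
        post = [gk.PersonPosterior(str(i), float(i), 1e-9, 3) for i in range(5)]
        assert gk.subject_separation(post) == pytest.approx(1.0, abs=1e-12)

    def test_no_separation(self):
        post = [gk.PersonPosterior(str(i), 0.7, 0.5, 3) for i in range(5)]
        assert gk.subject_separation(post) == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_scored_persons(self):
        with pytest.raises(InsufficientDataError):
            gk.subject_separation([gk.PersonPosterior("a", 0.0, 1.0, 2)])

    def test_reading_scale_separation_is_high(self, reading_recovery):
        _, rm, _, result = reading_recovery
        recoded = gk.apply_category_maps(rm, result.category_maps)
        post = gk.eap_scores(recoded, result.scale, result.grid)
        assert gk.subject_separation(post) >= 0.85
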