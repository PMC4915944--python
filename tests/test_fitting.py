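"""Tests of PSE prediction, the fast and trial-level fits, and prior reconstruction."""

import numpy as np
import pytest

import speedprior as sp
from speedprior.fitting import (
    FitConfig,
    _cdb_goodness,
    _vector_from_observer,
    fit_combined,
    fit_full_likelihood,
    fit_model,
    goodness_of_fit,
    predict_pse,
    predict_pse_var,
    predict_table,
    reconstruct_prior,
    trial_log_likelihood,
)
from speedprior.models import (
    ContrastResponse,
    LikelihoodModel,
    ObserverSpec,
    PriorModel,
    RatioParams,
)


def _condition(v_ref, c_ref, c_test):
    return sp.Condition(v_ref=v_ref, c_ref=c_ref, c_test=c_test)


class TestPredictPse:
    def test_zero_slopes_give_veridical_pse(self):
        obs = ObserverSpec(prior=PriorModel(knot_slopes=(0.0,) * 4))
        for v in (1.0, 4.0, 12.0):
            cond = _condition(v, 0.03, 0.95)
            assert predict_pse(obs, cond) == pytest.approx(v, abs=1e-8)

    def test_constant_slope_closed_form(self):
        # constant a and g: sigma depends only on contrast, so
        # v2 = v1 + a * (sigma1^2 - sigma2^2) exactly
        a, g = -0.2, 1.0
        obs = ObserverSpec(
            prior=PriorModel(knot_slopes=(a,) * 4),
            likelihood=LikelihoodModel(knot_g=(g,) * 4),
        )
        cond = _condition(4.0, 0.03, 0.95)
        h = obs.likelihood.contrast.gain
        expected = 4.0 + a * ((g * h(0.03)) ** 2 - (g * h(0.95)) ** 2)
        assert predict_pse(obs, cond) == pytest.approx(expected, abs=1e-8)

    def test_negative_slopes_predict_thompson_bias(self, observer, design):
        for cond in design.conditions:
            assert predict_pse(observer, cond) < cond.v_ref

    def test_non_invertible_condition_raises(self):
        # slope so steep that perceived speed never reaches the target
        obs = ObserverSpec(
            prior=PriorModel(knot_slopes=(-3.0,) * 4),
            likelihood=LikelihoodModel(knot_g=(10.0,) * 4),
        )
        with pytest.raises(ValueError, match="no PSE"):
            predict_pse(obs, _condition(8.0, 0.03, 0.95))

    def test_combined_variant_uses_front_end(self, design):
        obs = ObserverSpec(
            prior=PriorModel(knot_slopes=(0.0,) * 4), ratio=RatioParams()
        )
        cond = _condition(1.0, 0.03, 0.95)
        # at low speed the front end compresses high-contrast speed, so the
        # (high-contrast) test grating must move faster than under the plain model
        assert predict_pse(obs, cond, "combined") > predict_pse(obs, cond, "bayesian")


class TestPredictPseVar:
    def test_formula_and_linearity(self, observer):
        cond = _condition(4.0, 0.03, 0.95)
        config = FitConfig(alpha=1.0, n_trials=2)
        pse = predict_pse(observer, cond)
        s1 = sp.likelihood_sigma(observer.likelihood, cond.v_ref, cond.c_ref)
        s2 = sp.likelihood_sigma(observer.likelihood, pse, cond.c_test)
        assert predict_pse_var(observer, cond, config) == pytest.approx(
            (s1**2 + s2**2) / 2
        )
        # divisor N/alpha: alpha = 6, N = 36 gives (s1^2+s2^2)/6
        config6 = FitConfig(alpha=6.0, n_trials=36)
        assert predict_pse_var(observer, cond, config6) == pytest.approx(
            (s1**2 + s2**2) / 6
        )

    def test_doubling_sigma_squared_doubles_output(self, observer):
        cond = _condition(4.0, 0.03, 0.95)
        config = FitConfig()
        base = predict_pse_var(observer, cond, config, pse=4.0)
        scaled_obs = ObserverSpec(
            prior=observer.prior,
            likelihood=LikelihoodModel(
                knot_g=tuple(np.sqrt(2) * np.array(observer.likelihood.knot_g)),
                contrast=observer.likelihood.contrast,
            ),
        )
        assert predict_pse_var(scaled_obs, cond, config, pse=4.0) == pytest.approx(
            2 * base
        )


class TestReconstructPrior:
    def test_constant_slope_closed_form(self):
        a = -0.25
        prior = PriorModel(knot_slopes=(a,) * 4)
        grid = np.linspace(0.5, 14, 60)
        np.testing.assert_allclose(
            reconstruct_prior(prior, grid), np.exp(a * (grid - grid[0])), rtol=1e-12
        )

    def test_zero_slopes_give_flat_prior(self):
        prior = PriorModel(knot_slopes=(0.0,) * 4)
        np.testing.assert_allclose(reconstruct_prior(prior, [1, 2, 5, 9]), 1.0)

    def test_matches_refined_grid_oracle(self, observer):
        # grid containing the slope knots; a 20x-refined trapezoid oracle
        coarse = np.unique(
            np.concatenate([np.geomspace(0.5, 14, 40), observer.prior.knot_speeds])
        )
        fine = np.unique(
            np.concatenate(
                [
                    np.linspace(a, b, 21)
                    for a, b in zip(coarse[:-1], coarse[1:])
                ]
            )
        )
        coarse_density = reconstruct_prior(observer.prior, coarse)
        fine_density = reconstruct_prior(observer.prior, fine)
        idx = np.searchsorted(fine, coarse)
        np.testing.assert_allclose(coarse_density, fine_density[idx], rtol=1e-6)

    def test_normalized_to_one_at_grid_start(self, observer):
        assert reconstruct_prior(observer.prior, [2.0, 3.0])[0] == 1.0

    @pytest.mark.parametrize("grid", [[], [0.0, 1.0], [2.0, 1.0]])
    def test_bad_grids_rejected(self, observer, grid):
        with pytest.raises(ValueError):
            reconstruct_prior(observer.prior, grid)


class TestGoodnessOfFit:
    def test_perfect_predictions(self, observer, noise_free_table, noise_free_fit):
        out = goodness_of_fit(noise_free_fit, noise_free_table)
        assert out["sse"] == pytest.approx(0.0, abs=1e-12)
        assert out["r2"] == pytest.approx(1.0)

    def test_predicting_the_mean_gives_r2_zero(self):
        obs_cdb = np.array([0.8, 0.9, 1.0, 1.1])
        pred_cdb = np.full(4, obs_cdb.mean())
        sse, r2 = _cdb_goodness(obs_cdb, pred_cdb, np.ones(4))
        assert r2 == pytest.approx(0.0)
        assert sse == pytest.approx(np.sum((obs_cdb - obs_cdb.mean()) ** 2))

    def test_mismatched_conditions_rejected(self, noise_free_fit, pse_table):
        other = pse_table.copy()
        other["condition_id"] = other["condition_id"] + "_x"
        with pytest.raises(ValueError, match="different conditions"):
            goodness_of_fit(noise_free_fit, other)


class TestFastFit:
    def test_noise_free_self_consistency(self, observer, noise_free_fit, design):
        """Refitting the model's own predictions recovers it exactly.

        a(v) * sigma^2(v, c) products (the identifiable quantities, given the
        g/h scale degeneracy) must match the generator's to well under 1%.
        """
        assert noise_free_fit.cost < 1e-12
        assert noise_free_fit.sse == pytest.approx(0.0, abs=1e-12)

        def products(obs):
            vals = []
            for cond in design.conditions:
                for v, c in ((cond.v_ref, cond.c_ref), (cond.v_ref, cond.c_test)):
                    a = sp.slope_at(obs.prior, v)
                    s = sp.likelihood_sigma(obs.likelihood, v, c)
                    vals.append(a * s * s)
            return np.array(vals)

        rel = np.abs(products(noise_free_fit.observer) - products(observer)) / np.abs(
            products(observer)
        )
        assert rel.max() <= 0.01

    def test_recovers_slope_signs_and_ordering(self, observer, recovery_fit):
        fitted = np.array(recovery_fit.observer.prior.knot_slopes)
        true = np.array(observer.prior.knot_slopes)
        assert np.all(np.sign(fitted) == np.sign(true))
        # generator slopes shallow with speed; recovered ones do too
        assert np.all(np.diff(fitted) > 0) == np.all(np.diff(true) > 0)

    def test_deterministic_under_seed(self, noise_free_table):
        cfg = FitConfig(n_multistart=2)
        a = fit_model(noise_free_table, cfg)
        b = fit_model(noise_free_table, cfg)
        assert a.observer == b.observer
        assert a.cost == b.cost and a.best_start == b.best_start

    def test_too_few_conditions_rejected(self, noise_free_table):
        with pytest.raises(ValueError, match="identifiable"):
            fit_model(noise_free_table.iloc[:6], FitConfig(n_multistart=1))


@pytest.fixture(scope="module")
def ratio_observer():
    return ObserverSpec(ratio=RatioParams())


@pytest.fixture(scope="module")
def ratio_table(ratio_observer, design):
    cfg = FitConfig(variant="combined", ratio=RatioParams())
    return predict_table(ratio_observer, design.conditions, cfg)


class TestCombinedFit:
    def test_identity_candidate_reproduces_fit_model(self, noise_free_table):
        cfg = FitConfig(n_multistart=3)
        plain = fit_model(noise_free_table, cfg)
        degenerate = fit_combined(noise_free_table, cfg, ratio_candidates=[None])
        assert degenerate.observer == plain.observer
        assert degenerate.cost == plain.cost

    def test_fixed_ratio_keeps_ten_free_parameters(self, ratio_table):
        cfg = FitConfig(n_multistart=3)
        fit = fit_combined(ratio_table, cfg, ratio_candidates=[RatioParams()])
        assert len(_vector_from_observer(fit.observer)) == 10
        assert fit.observer.ratio == RatioParams()
        assert fit.variant == "combined"

    def test_combined_beats_bayesian_on_ratio_generated_data(self, ratio_table):
        """The nested model nests the plain one, so with the true front end it
        fits ratio-generated (noise-free) predictions strictly better."""
        cfg = FitConfig(n_multistart=6)
        bayes = fit_model(ratio_table, cfg)
        comb = fit_combined(ratio_table, cfg, ratio_candidates=[RatioParams()])
        assert comb.sse <= bayes.sse
        assert comb.sse == pytest.approx(0.0, abs=1e-10)
        assert bayes.sse > 1e-4  # the front end is not absorbable by the prior
        np.testing.assert_allclose(
            comb.observer.prior.knot_slopes, (-0.3, -0.15, -0.08, -0.05), atol=1e-6
        )

    def test_nested_search_smoke(self, ratio_table):
        """A tiny-budget outer search still lands on a good shared front end
        (the published optimum is always among the starting points)."""
        cfg = FitConfig(
            n_multistart=2,
            outer_coarse_n=1,
            outer_refine_iters=4,
            inner_multistart_search=1,
        )
        fit = fit_combined(ratio_table, cfg)
        assert fit.variant == "combined"
        r = fit.observer.ratio
        assert cfg.outer_s_bounds[0] <= r.s_p <= cfg.outer_s_bounds[1]
        assert cfg.outer_k_bounds[0] <= r.k <= cfg.outer_k_bounds[1]
        # must beat a deliberately wrong fixed front end
        wrong = fit_combined(
            ratio_table, cfg, ratio_candidates=[RatioParams.literature()]
        )
        assert fit.cost <= wrong.cost


class TestFullLikelihood:
    def test_generating_parameters_near_optimal(self, observer, dataset, full_likelihood_fit):
        trials = sp.experiment.trials_to_frame(dataset)
        ll_truth = trial_log_likelihood(observer, trials)
        perturbed = ObserverSpec(
            prior=PriorModel(
                knot_slopes=tuple(1.5 * np.array(observer.prior.knot_slopes))
            ),
            likelihood=observer.likelihood,
        )
        ll_perturbed = trial_log_likelihood(perturbed, trials)
        assert full_likelihood_fit.loglik >= ll_truth >= ll_perturbed

    def test_deterministic_under_seed(self, dataset):
        trials = sp.experiment.trials_to_frame(dataset).iloc[:1500]
        cfg = FitConfig(n_multistart=2)
        a = fit_full_likelihood(trials, cfg)
        b = fit_full_likelihood(trials, cfg)
        assert a.observer == b.observer and a.cost == b.cost

    def test_recovers_slope_signs(self, observer, full_likelihood_fit):
        fitted = np.array(full_likelihood_fit.observer.prior.knot_slopes)
        assert np.all(np.sign(fitted) == np.sign(observer.prior.knot_slopes))
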