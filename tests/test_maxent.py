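"""Maximum-entropy fit: closed forms, oracles, recovery and invariants."""
import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import spearmanr

import enmrisk as e
from enmrisk.maxent import sample_background


@pytest.fixture(scope="module")
def fitted_ensemble(presence_sample, small_stack):
    return e.fit_bootstrap(presence_sample, small_stack, n_reps=8,
                           n_background=2000, seed=21)


class TestBuildFeatures:
    def test_minmax_scaling_arithmetic(self, small_stack):
        fs = e.FeatureSpec(["v"], np.array([0.0]), np.array([10.0]))
        F = fs.transform(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(F[:, 0], [0, 0.5, 1])
        np.testing.assert_allclose(F[:, 1], [0, 0.25, 1])

    def test_feature_order_linear_then_quadratic(self, small_stack):
        bg = sample_background(small_stack, 500, np.random.default_rng(0))
        fs = e.build_features(small_stack, ["bio01", "bio12"], bg)
        assert fs.feature_names == ["bio01", "bio12", "bio01^2", "bio12^2"]

    def test_projection_outside_bounds_is_clamped(self):
        fs = e.FeatureSpec(["v"], np.array([0.0]), np.array([10.0]))
        F = fs.transform(np.array([[12.0], [-3.0]]))
        np.testing.assert_allclose(F, [[1, 1], [0, 0]])

    def test_constant_predictor_rejected(self, small_stack):
        st = e.ClimateStack(small_stack.grid, ["flat"],
                            np.zeros((1,) + small_stack.grid.shape))
        with pytest.raises(ValueError, match="degenerate"):
            e.build_features(st, ["flat"], st.valid_cell_indices()[:100])


class TestFitMaxent:
    def test_uniform_presences_shrink_to_zero(self, small_stack):
        rng = np.random.default_rng(1)
        bg = sample_background(small_stack, 2000, rng)
        fs = e.build_features(small_stack, small_stack.names, bg)
        F_bg = fs.transform(small_stack.values_at_cells(bg, small_stack.names))
        pres = rng.choice(len(F_bg), 500, replace=False)
        fit = e.fit_maxent(F_bg[pres], F_bg)
        # presence-mean noise can leak through the L1 gate amplified by the
        # inverse feature curvature, so weights are small but not < noise sd;
        # the fitted distribution itself must stay essentially uniform
        assert np.max(np.abs(fit.lam)) < 0.5
        assert np.log(len(F_bg)) - fit.entropy_H < 0.02  # KL(raw || uniform)
        assert fit.training_auc == pytest.approx(0.5, abs=0.05)

    def test_huge_regularisation_gives_uniform_model(self, small_stack):
        rng = np.random.default_rng(2)
        bg = sample_background(small_stack, 1000, rng)
        fs = e.build_features(small_stack, small_stack.names, bg)
        F_bg = fs.transform(small_stack.values_at_cells(bg, small_stack.names))
        fit = e.fit_maxent(F_bg[:50], F_bg, reg_multiplier=1e6)
        np.testing.assert_array_equal(fit.lam, 0.0)
        assert fit.entropy_H == pytest.approx(np.log(len(F_bg)))

    def test_one_feature_moment_condition_against_bisection_oracle(self):
        """With 3 background cells f in {0, .5, 1} and presence mean 0.8,
        the unpenalised optimum solves E_lambda[f] = 0.8."""
        F_b = np.array([[0.0], [0.5], [1.0]])
        F_p = np.array([[0.8], [0.8]])
        fit = e.fit_maxent(F_p, F_b, reg_multiplier=0.0, max_iterations=2000)

        def moment(lam):
            w = np.exp(lam * F_b[:, 0])
            return (F_b[:, 0] * w).sum() / w.sum() - 0.8
        lam_star = brentq(moment, -50, 50)
        assert fit.lam[0] == pytest.approx(lam_star, abs=1e-3)

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            e.fit_maxent(np.array([[np.nan], [0.5]]), np.zeros((5, 1)))

    def test_raw_distribution_normalises(self, fitted_ensemble, small_stack):
        fs = fitted_ensemble.feature_spec
        F_bg = fs.transform(small_stack.values_at_cells(
            fitted_ensemble.background_cells, fs.variable_names))
        for fit in fitted_ensemble.replicates[:3]:
            p = np.exp(F_bg @ fit.lam - fit.log_partition)
            assert abs(p.sum() - 1.0) < 1e-8

    def test_objective_never_increases(self, fitted_ensemble):
        for fit in fitted_ensemble.replicates:
            trace = np.array(fit.objective_trace)
            assert np.all(np.diff(trace) <= 1e-9)

    def test_training_auc_above_half_for_selective_species(self, fitted_ensemble):
        assert fitted_ensemble.auc_mean >= 0.5 - 0.02


class TestPredictCloglog:
    def test_uniform_model_gives_1_minus_1_over_e(self):
        F_b = np.linspace(0, 1, 10)[:, None]
        fit = e.fit_maxent(F_b[:5], F_b, reg_multiplier=1e6)
        suit = e.predict_cloglog(fit, F_b)
        np.testing.assert_allclose(suit, 1 - np.exp(-1), atol=1e-12)

    def test_monotone_in_linear_predictor(self):
        # parameters chosen so the cloglog stays clear of float saturation
        fit = e.ModelFit(["f"], np.array([3.0]), 3.0, 0.5, 0.5, 1)
        F = np.linspace(0, 1, 50)[:, None]
        suit = e.predict_cloglog(fit, F)
        assert np.all(np.diff(suit) > 0)
        assert np.all((suit >= 0) & (suit <= 1))

    def test_equal_features_equal_suitability(self):
        fit = e.ModelFit(["f"], np.array([2.0]), 0.3, 1.1, 0.5, 1)
        suit = e.predict_cloglog(fit, np.array([[0.4], [0.4]]))
        assert suit[0] == suit[1]


class TestAuc:
    @pytest.mark.parametrize("pres, bg, expected", [
        ([0.9, 0.8], [0.7, 0.4, 0.1], 1.0),
        ([0.3, 0.6, 0.9], [0.3, 0.6, 0.9], 0.5),
        ([0.6], [0.4, 0.8], 0.5),
    ])
    def test_hand_examples(self, pres, bg, expected):
        assert e.auc(pres, bg) == pytest.approx(expected)

    def test_agrees_with_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        pres = rng.beta(3, 2, 40)
        bg = rng.beta(2, 3, 100)
        y = np.r_[np.ones(40), np.zeros(100)]
        assert e.auc(pres, bg) == pytest.approx(
            roc_auc_score(y, np.r_[pres, bg]))


class TestFitBootstrap:
    def test_single_replicate_mean_is_that_replicate(self, presence_sample,
                                                     small_stack):
        ens = e.fit_bootstrap(presence_sample, small_stack, n_reps=1,
                              n_background=1000, seed=4)
        fs = ens.feature_spec
        valid = small_stack.valid_cell_indices()
        F = fs.transform(small_stack.values_at_cells(valid, fs.variable_names))
        expected = e.predict_cloglog(ens.replicates[0], F)
        np.testing.assert_allclose(ens.mean_map.ravel()[valid], expected)

    def test_deterministic(self, presence_sample, small_stack):
        a = e.fit_bootstrap(presence_sample, small_stack, n_reps=2,
                            n_background=800, seed=9)
        b = e.fit_bootstrap(presence_sample, small_stack, n_reps=2,
                            n_background=800, seed=9)
        np.testing.assert_array_equal(a.mean_map, b.mean_map)

    def test_background_smaller_than_presences_rejected(self, presence_sample,
                                                        small_stack):
        with pytest.raises(ValueError, match="background"):
            e.fit_bootstrap(presence_sample, small_stack, n_reps=1,
                            n_background=50, seed=0)

    def test_recovers_true_suitability_ranking(self, fitted_ensemble,
                                               selective_species, small_stack):
        m = small_stack.mask
        rho = spearmanr(fitted_ensemble.mean_map[m],
                        selective_species.true_suitability[m]).statistic
        assert rho > 0.9


class TestSignRecovery:
    def test_fitted_quadratic_sign_matches_truth(self, small_stack):
        """Bell-shaped planted niches (quadratic coefficient b <= -2, the
        canonical unimodal climate response) yield a negative fitted
        quadratic weight in >= 90% of simulations.

        Convex niches (b > 0) are excluded: the cloglog response caps their
        presence-sampling contrast at (1 - 1/e)^-1 ~ 1.6:1, so their
        curvature carries almost no recoverable signal.
        """
        hits = trials = 0
        bg = sample_background(small_stack, 2000, np.random.default_rng(3))
        fs = e.build_features(small_stack, ["bio01"], bg)
        F_bg = fs.transform(small_stack.values_at_cells(bg, ["bio01"]))
        for rep in range(50):
            b_true = -float(np.random.default_rng(900 + rep).uniform(2, 6))
            vs = e.make_virtual_species(small_stack, {}, {"bio01": b_true})
            occ = e.sample_occurrences(vs, 200, seed=500 + rep)
            lonlat = occ.kept_lonlat()
            r, c = small_stack.grid.cell_of(lonlat[:, 0], lonlat[:, 1])
            F_p = fs.transform(small_stack.values_at_cells(
                r * small_stack.grid.n_cols + c, ["bio01"]))
            fit = e.fit_maxent(F_p, F_bg, reg_multiplier=1.0)
            trials += 1
            hits += fit.lam[1] < 0
        assert hits / trials >= 0.9


class TestResponseCurve:
    def test_zero_model_is_flat(self, small_stack):
        fs = e.FeatureSpec(["v", "w"], np.zeros(2), np.ones(2))
        fit = e.ModelFit(fs.feature_names, np.zeros(4), np.log(100), np.log(100), 0.5, 1)
        _, suit = e.response_curve(fit, fs, "v", 20)
        assert np.allclose(suit, suit[0])

    def test_positive_linear_weight_is_increasing(self):
        fs = e.FeatureSpec(["v"], np.zeros(1), np.ones(1))
        fit = e.ModelFit(fs.feature_names, np.array([2.0, 0.0]),
                         np.log(50), np.log(50), 0.5, 1)
        _, suit = e.response_curve(fit, fs, "v", 30)
        assert np.all(np.diff(suit) > 0)

    def test_negative_quadratic_peaks_at_analytic_optimum(self):
        # eta(z) = a z + b z^2 peaks at z* = -a / (2b)
        a, b = 3.0, -4.0
        fs = e.FeatureSpec(["v"], np.zeros(1), np.ones(1))
        fit = e.ModelFit(fs.feature_names, np.array([a, b]),
                         np.log(50), np.log(50), 0.5, 1)
        values, suit = e.response_curve(fit, fs, "v", 501)
        z_star = np.clip(-a / (2 * b), 0, 1)
        assert values[np.argmax(suit)] == pytest.approx(z_star, abs=0.01)
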