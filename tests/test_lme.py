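import numpy as np
import pytest

from protraj.lme import (
    LMEDesign,
    fit_lme,
    fit_random_intercept,
    gls_beta_blups,
    predict_features,
    reml_fit,
)

from oracles import henderson_blups, random_intercept_scores_closed_form


def _balanced_toy(n_patients=20, times=(0.0, 0.5, 1.0), seed=4,
                  beta=(1.0, -0.5), D=((0.4, 0.1), (0.1, 0.2)), sigma=0.3):
    rng = np.random.default_rng(seed)
    D = np.asarray(D)
    b = rng.multivariate_normal([0, 0], D, size=n_patients)
    t = np.asarray(times)
    ts, ys = [], []
    for i in range(n_patients):
        y = (beta[0] + b[i, 0]) + (beta[1] + b[i, 1]) * t + rng.normal(0, sigma, len(t))
        ts.append(t.copy())
        ys.append(y)
    return ts, ys


def _design(ts, ys):
    codes = np.concatenate([np.full(len(t), i) for i, t in enumerate(ts)])
    return LMEDesign(codes, np.concatenate(ts)), np.concatenate(ys)


class TestRemlFit:
    def test_noiseless_common_line(self):
        """y = 1 + 2t for everyone: exact fixed effects, vanishing noise,
        every patient's features equal (1, 2)."""
        t = np.array([0.0, 0.5, 1.0])
        groups = [(t, 1.0 + 2.0 * t) for _ in range(6)]
        fit = fit_lme(groups)
        np.testing.assert_allclose(fit.beta, [1.0, 2.0], atol=1e-8)
        assert fit.sigma2 < 1e-10
        for t_i, y_i in groups:
            a, s = predict_features(fit, t_i, y_i)
            assert abs(a - 1.0) < 1e-6 and abs(s - 2.0) < 1e-6

    def test_blups_match_henderson_equations(self):
        """The Woodbury per-patient path equals the dense mixed-model
        equations at the same variance components (max abs diff < 1e-6)."""
        ts, ys = _balanced_toy()
        design, y = _design(ts, ys)
        fit, feats = reml_fit(design, y)
        G = fit.D / fit.sigma2
        beta_o, feats_o = henderson_blups(ts, ys, G)
        np.testing.assert_allclose(fit.beta, beta_o, atol=1e-6)
        np.testing.assert_allclose(feats, feats_o, atol=1e-6)

    def test_gls_helper_matches_henderson_at_fixed_components(self):
        ts, ys = _balanced_toy(seed=8)
        design, y = _design(ts, ys)
        G = np.array([[2.0, 0.3], [0.3, 1.0]])
        beta, feats = gls_beta_blups(design, y, G)
        beta_o, feats_o = henderson_blups(ts, ys, G)
        np.testing.assert_allclose(beta, beta_o, atol=1e-8)
        np.testing.assert_allclose(feats, feats_o, atol=1e-8)

    def test_simulation_recovery_of_fixed_effects(self):
        """Over replicates the mean estimates sit within 3 MC SE of truth."""
        b0s, b1s = [], []
        for seed in range(40):
            ts, ys = _balanced_toy(n_patients=120, seed=seed, beta=(0.8, -0.4))
            design, y = _design(ts, ys)
            fit, _ = reml_fit(design, y)
            b0s.append(fit.beta[0])
            b1s.append(fit.beta[1])
        for est, truth in ((b0s, 0.8), (b1s, -0.4)):
            se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(np.mean(est) - truth) < 3 * se + 1e-12

    def test_criterion_path_non_increasing(self):
        ts, ys = _balanced_toy(seed=2)
        design, y = _design(ts, ys)
        fit, _ = reml_fit(design, y)
        path = fit.criterion_path
        assert len(path) > 1
        assert np.all(np.diff(path) <= 1e-12)

    def test_wald_coverage_for_slope(self):
        """95% Wald intervals for the fixed slope cover the truth at a
        nominal-ish rate across simulated proteins."""
        hits = 0
        n = 100
        for seed in range(n):
            ts, ys = _balanced_toy(n_patients=60, seed=1000 + seed, beta=(0.0, 0.7))
            design, y = _design(ts, ys)
            fit, _ = reml_fit(design, y)
            lo = fit.beta[1] - 1.96 * fit.beta_se[1]
            hi = fit.beta[1] + 1.96 * fit.beta_se[1]
            hits += lo <= 0.7 <= hi
        assert 0.90 <= hits / n <= 0.99

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_lme([(np.array([0.0]), np.array([1.0])),
                     (np.array([0.5]), np.array([2.0]))])

    def test_constant_values_flagged_degenerate(self):
        t = np.array([0.0, 0.5, 1.0])
        fit = fit_lme([(t, np.full(3, 2.5)) for _ in range(4)])
        assert fit.degenerate
        np.testing.assert_allclose(fit.beta, [2.5, 0.0])

    def test_intercept_only_fallback_when_slope_variance_vanishes(self):
        """Pure random-intercept data triggers the intercept-only refit."""
        rng = np.random.default_rng(3)
        t = np.array([0.0, 0.5, 1.0])
        # every patient has exactly the common slope: only the intercept varies
        groups = [(t, 1.0 + rng.normal(0, 1.0) + 0.5 * t + rng.normal(0, 1e-6, 3))
                  for _ in range(40)]
        fit = fit_lme(groups)
        assert fit.model_form == "intercept_only"
        assert fit.D[1, 1] == 0.0
        a, s = predict_features(fit, t, groups[0][1])
        assert s == pytest.approx(fit.beta[1])


class TestPredictFeatures:
    def test_single_observation_shrinks_to_population(self):
        ts, ys = _balanced_toy(seed=6)
        design, y = _design(ts, ys)
        fit, _ = reml_fit(design, y)
        a, s = predict_features(fit, [0.5], [100.0])
        # far-out value is shrunk: prediction stays finite and between
        # the population line and the raw observation
        pop = fit.beta[0] + fit.beta[1] * 0.5
        assert pop < a + s * 0.5 < 100.0

    def test_no_observations_returns_population_line(self):
        ts, ys = _balanced_toy(seed=6)
        design, y = _design(ts, ys)
        fit, _ = reml_fit(design, y)
        assert predict_features(fit, [], []) == (pytest.approx(fit.beta[0]),
                                                 pytest.approx(fit.beta[1]))

    def test_many_observations_approach_own_least_squares_line(self):
        """With tiny residual noise the BLUP equals the patient's own line."""
        rng = np.random.default_rng(9)
        t = np.linspace(0, 2, 30)
        groups = [(t, (1 + rng.normal(0, 0.6)) + (0.3 + rng.normal(0, 0.3)) * t
                   + rng.normal(0, 1e-4, len(t))) for _ in range(10)]
        fit = fit_lme(groups)
        t0, y0 = groups[0]
        own = np.polyfit(t0, y0, 1)
        a, s = predict_features(fit, t0, y0)
        assert abs(a - own[1]) < 1e-3 and abs(s - own[0]) < 1e-3


class TestRandomIntercept:
    def test_matches_balanced_closed_form(self):
        rng = np.random.default_rng(12)
        n, P = 25, 8
        x = rng.normal(0, 1, size=(n, 1)) + rng.normal(0, 0.5, size=(n, P))
        codes = np.repeat(np.arange(n), P)
        fit = fit_random_intercept(x.ravel(), codes)
        oracle = random_intercept_scores_closed_form(x)
        np.testing.assert_allclose(fit.scores, oracle, atol=1e-8)

    def test_noiseless_scores_equal_patient_values(self):
        n, P = 10, 6
        c = np.linspace(-2, 2, n)
        x = np.tile(c[:, None], (1, P)) + 1e-9 * np.arange(P)
        fit = fit_random_intercept(x.ravel(), np.repeat(np.arange(n), P))
        np.testing.assert_allclose(fit.scores, c, atol=1e-6)

    def test_collapsed_variance_flags_and_returns_grand_mean(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5.0, 1.0, size=(30, 4))  # no patient effect
        x -= x.mean(axis=1, keepdims=True) - x.mean()  # force identical means
        fit = fit_random_intercept(x.ravel(), np.repeat(np.arange(30), 4))
        assert fit.collapsed
        assert np.allclose(fit.scores, fit.mu)
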