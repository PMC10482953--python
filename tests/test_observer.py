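"""Unit and property tests for the generative observer equations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from priorconf.observer import (
    InvalidParameterError,
    ObserverParams,
    StimulusSpec,
    confidence_likelihood,
    confidence_prior,
    lead_confidence,
    normalize_stimulus,
    p_right_target,
    posterior_confidence_right,
    shifted_criterion,
    simulate_trial,
    simulate_trials,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


class TestNormalization:
    @pytest.mark.parametrize(
        "direction, coh, bias, sigma, expected",
        [
            (+1, 0.15, 0.0, 0.1, 1.5),
            (-1, 0.10, 0.02, 0.12, -1.0),
            (+1, 0.05, 0.05, 0.3, 0.0),
        ],
    )
    def test_normalized_strength(self, direction, coh, bias, sigma, expected):
        s = normalize_stimulus(StimulusSpec(direction, coh), sigma, bias)
        assert s == pytest.approx(expected)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            normalize_stimulus(StimulusSpec(1, 0.1), 0.0, 0.0)

    def test_invalid_stimulus_rejected(self):
        with pytest.raises(InvalidParameterError):
            StimulusSpec(0, 0.1)
        with pytest.raises(InvalidParameterError):
            StimulusSpec(1, 1.2)


class TestElementaryEquations:
    def test_lead_confidence_values(self):
        assert lead_confidence(0.0) == pytest.approx(0.5)
        assert lead_confidence(1.0) == pytest.approx(0.8413, abs=1e-4)
        assert lead_confidence(-2.0) == pytest.approx(lead_confidence(2.0))
        assert np.all(lead_confidence(np.linspace(-3, 3, 13)) >= 0.5)

    def test_criterion_shift(self):
        assert shifted_criterion(2.0, 1.0) == pytest.approx(-2.0)
        assert shifted_criterion(2.0, 1e9) == pytest.approx(0.0, abs=1e-8)
        assert shifted_criterion(0.0, 0.7) == 0.0
        with pytest.raises(InvalidParameterError):
            shifted_criterion(1.0, 0.0)

    def test_confidence_prior_values(self):
        assert confidence_prior(0.0, 1.0, 1.0) == pytest.approx(0.5)
        assert confidence_prior(1.0, 1.0, 1.0) == pytest.approx(0.8413, abs=1e-4)
        assert confidence_prior(1.0, 2.0, 2.0) == pytest.approx(
            norm.cdf(0.25), abs=1e-4)
        # agrees with lead confidence exactly when b * w_conf = 1
        r = np.linspace(-3, 3, 21)
        np.testing.assert_allclose(confidence_prior(r, 2.0, 0.5),
                                   lead_confidence(r))

    def test_confidence_likelihood_values(self):
        assert confidence_likelihood(0.0, 1.0) == pytest.approx(0.5)
        assert confidence_likelihood(1.0, 1.0) == pytest.approx(0.8413, abs=1e-4)
        assert confidence_likelihood(1.0, 1e9) == pytest.approx(0.5, abs=1e-6)

    def test_posterior_combination_hand_value(self):
        assert posterior_confidence_right(0.8, 0.75) == pytest.approx(
            0.9231, abs=1e-4)

    @given(st.floats(0.01, 0.99))
    def test_flat_prior_identity(self, x):
        assert posterior_confidence_right(0.5, x) == pytest.approx(x, abs=1e-9)

    @given(st.floats(0.01, 0.99))
    def test_uninformative_likelihood_identity(self, p):
        assert posterior_confidence_right(p, 0.5) == pytest.approx(p, abs=1e-9)

    def test_extreme_inputs_clamped_not_nan(self):
        out = posterior_confidence_right(np.array([0.0, 1.0]),
                                         np.array([1.0, 0.0]))
        assert np.all(np.isfinite(out))


class TestMarginalChoiceProbability:
    def test_flat_prior_limit(self):
        got = p_right_target(1.0, 0.5, 1, 1e6)
        assert got == pytest.approx(norm.cdf(0.5), abs=1e-4)

    def test_against_monte_carlo(self, rng):
        # brute-force marginalization over the truncated lead response
        for s_lead, s_target, choice in [(1.0, 0.5, 1), (0.5, -0.5, -1),
                                         (2.0, 1.0, 1)]:
            r = rng.normal(choice * s_lead, 1.0, size=4_000_000)
            r = r[r > 0][:1_500_000]
            mc = norm.cdf(s_target + r / 2.0).mean()
            assert p_right_target(s_lead, s_target, choice, 2.0) == pytest.approx(
                mc, abs=1e-3)

    def test_strong_target_limit(self):
        assert p_right_target(1.0, 30.0, 1, 2.0) > 1 - 1e-6

    @given(st.floats(-2, 2), st.floats(-1, 1), st.floats(0.3, 5))
    def test_monotone_in_target_strength(self, s_lead, s_target, w):
        lo = p_right_target(s_lead, s_target, 1, w)
        hi = p_right_target(s_lead, s_target + 0.5, 1, w)
        assert hi >= lo

    def test_monotone_in_lead_strength_correct_lead(self):
        vals = [p_right_target(s, 0.3, 1, 2.0) for s in (0.2, 0.8, 1.5, 2.5)]
        assert np.all(np.diff(vals) > 0)


class TestSimulation:
    def test_chance_lead_accuracy_at_zero_signal(self, rng):
        p = ObserverParams(sigma=0.1, bias=0.0)
        out = simulate_trials(p, rng.choice([-1, 1], 20000),
                              np.full(20000, 1e-9), np.full(20000, 0.1), rng)
        assert out["lead_correct"].mean() == pytest.approx(0.5, abs=0.02)

    def test_task_rule_conservation(self, rng):
        p = ObserverParams(sigma=0.1, lapse=0.1)
        out = simulate_trials(p, rng.choice([-1, 1], 5000),
                              np.full(5000, 0.1), np.full(5000, 0.1), rng)
        np.testing.assert_array_equal(
            out["target_dir"], np.where(out["lead_correct"], 1, -1))

    def test_underweighting_favors_stronger_target(self, rng):
        # matched condition pair at one posterior level, prior underweighted
        p = ObserverParams(w_choice=3.0, w_conf=3.0, sigma=0.1)
        n = 30000
        accs = {}
        for cond, (lead_c, targ_c) in {"SL": (0.15, 0.06),
                                       "ST": (0.06, 0.15)}.items():
            out = simulate_trials(p, rng.choice([-1, 1], n),
                                  np.full(n, lead_c), np.full(n, targ_c), rng)
            accs[cond] = out["target_correct"].mean()
        assert accs["ST"] - accs["SL"] > 0.02

    def test_report_clipped_to_scale(self, rng):
        # mismatched weights can push confidence in the chosen option < 0.5
        p = ObserverParams(w_choice=0.3, w_conf=5.0, sigma=0.1)
        out = simulate_trials(p, rng.choice([-1, 1], 5000),
                              np.full(5000, 0.1), np.full(5000, 0.05), rng)
        assert out["conf_model"].min() < 0.5  # pre-clip value retained
        assert out["conf_report"].min() >= 0.5
        assert out["conf_report"].max() <= 1.0

    def test_single_trial_api(self):
        p = ObserverParams(sigma=0.1)
        t = simulate_trial(p, StimulusSpec(1, 0.15, "H"), 0.1, rng=7)
        assert t.lead_choice in (-1, 1)
        assert 0.5 <= t.conf_report <= 1.0
        assert t.internal.r_lead == t.internal.r_lead  # finite latent state

    def test_metacog_noise_unbiased_to_first_order(self, rng):
        # mean-zero metacognitive noise jitters the confidence prior across
        # trials without biasing its mean to first order (small-noise regime)
        n, sd = 10_000, 0.3
        r = rng.normal(1.0, 1.0, n)
        eps = rng.normal(0.0, sd, n)
        clean = confidence_prior(r, 1.0, 1.0)
        noised = confidence_prior(r + eps, 1.0, 1.0)
        se = np.sqrt(clean.var() / n + noised.var() / n)
        assert abs(noised.mean() - clean.mean()) < 3 * se
        assert noised.std() > clean.std()  # more variable, as intended

    def test_metacog_noise_families_alter_confidence_only(self, rng):
        base = ObserverParams(sigma=0.1)
        n = 5000
        dirs = rng.choice([-1, 1], n)
        lead, targ = np.full(n, 0.1), np.full(n, 0.1)
        for fam in ("gaussian", "lognormal"):
            noisy = base.with_(metacog_noise_sd=0.4, metacog_noise_family=fam)
            out0 = simulate_trials(base, dirs, lead, targ,
                                   np.random.default_rng(5))
            out1 = simulate_trials(noisy, dirs, lead, targ,
                                   np.random.default_rng(5))
            # identical first-order behaviour (same rng stream before noise)
            np.testing.assert_array_equal(out0["target_choice"],
                                          out1["target_choice"])
            assert not np.allclose(out0["conf_model"], out1["conf_model"])

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidParameterError):
            ObserverParams(w_choice=-1.0)
        with pytest.raises(InvalidParameterError):
            ObserverParams(lapse=0.7)
        with pytest.raises(InvalidParameterError):
            ObserverParams(metacog_noise_family="cauchy")
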