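"""Tests of likelihood construction and Bayesian estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from priorconf.fitting import (
    ParticipantData,
    SamplerConfig,
    _p_right_quad,
    choice_loglik,
    confidence_loglik,
    exclude_outliers,
    fit_hierarchical,
    fit_individual,
    predicted_confidence,
    resample_from_simplified,
)
from priorconf.observer import p_right_target
from priorconf.evaluate import make_cohort_params, simulate_and_normalize
from priorconf.synthetic import ExperimentDesign


def toy_table(n=40, seed=0, both_choices=True):
    rng = np.random.default_rng(seed)
    lead_dir = rng.choice([-1, 1], n)
    target_dir = rng.choice([-1, 1], n)
    levels = np.array(["L", "M", "H"])
    df = pd.DataFrame({
        "participant": "p1",
        "lead_dir": lead_dir,
        "target_dir": target_dir,
        "lead_level": rng.choice(levels, n),
        "target_level": rng.choice(levels, n),
        "lead_choice": rng.choice([-1, 1], n),
        "target_choice": rng.choice([-1, 1], n),
        "conf_report": rng.uniform(0.5, 1.0, n),
    })
    mag = {"L": 0.6, "M": 1.0, "H": 1.5}
    df["s_lead_norm"] = df["lead_dir"] * df["lead_level"].map(mag)
    df["s_target_norm"] = df["target_dir"] * df["target_level"].map(mag)
    return df


PARAMS = {"w_choice": 2.0, "w_conf": 1.3, "b": 1.8, "report_noise_sd": 0.12}


class TestChoiceLikelihood:
    @pytest.mark.parametrize("model", ["flexible", "flat_prior", "optimal"])
    @pytest.mark.parametrize("simplified", [False, True])
    def test_probabilities_sum_to_one(self, model, simplified):
        df = toy_table()
        ll_obs = choice_loglik(df, PARAMS, model, simplified)
        flipped = df.assign(target_choice=-df["target_choice"])
        ll_flip = choice_loglik(flipped, PARAMS, model, simplified)
        np.testing.assert_allclose(np.exp(ll_obs) + np.exp(ll_flip), 1.0,
                                   atol=1e-9)

    def test_flat_prior_closed_form(self):
        df = toy_table()
        ll = choice_loglik(df, PARAMS, "flat_prior")
        expected = norm.logcdf(df["target_choice"] * df["s_target_norm"])
        np.testing.assert_allclose(ll, expected, atol=1e-9)

    def test_flat_prior_ignores_lead_information(self):
        df = toy_table(200, seed=3)
        ll = choice_loglik(df, PARAMS, "flat_prior").sum()
        permuted = df.copy()
        perm = np.random.default_rng(0).permutation(len(df))
        for col in ("s_lead_norm", "lead_dir", "lead_level", "lead_choice"):
            permuted[col] = df[col].to_numpy()[perm]
        assert choice_loglik(permuted, PARAMS, "flat_prior").sum() == \
            pytest.approx(ll, abs=1e-9)

    def test_full_vs_monte_carlo_oracle(self):
        # brute-force marginalization over the truncated lead response
        rng = np.random.default_rng(42)
        for s_lead in (0.5, 1.0, 2.0):
            for s_target in (-0.5, 0.5, 1.5):
                for choice in (1, -1):
                    r = rng.normal(s_lead, 1.0, 4_000_000)
                    r = r[np.sign(r) == choice][:1_000_000]
                    mc = norm.cdf(s_target + np.abs(r) / 2.0).mean()
                    q = _p_right_quad(np.array([s_lead]), np.array([s_target]),
                                      np.array([choice]), np.array([2.0]))
                    assert q[0] == pytest.approx(mc, abs=1e-3)

    def test_fitting_quadrature_matches_reference(self):
        grid = [(s, t, c, w) for s in (0.3, 1.0, 2.5) for t in (-1.0, 0.5)
                for c in (-1, 1) for w in (0.5, 2.0)]
        for s, t, c, w in grid:
            assert _p_right_quad(np.array([s]), np.array([t]), np.array([c]),
                                 np.array([w]))[0] == pytest.approx(
                p_right_target(s, t, c, w), abs=1e-6)

    def test_simplified_converges_to_full_at_large_w(self):
        df = toy_table()
        big = {**PARAMS, "w_choice": 1e6}
        full = choice_loglik(df, big, "flexible", use_simplification=False)
        simp = choice_loglik(df, big, "flexible", use_simplification=True)
        np.testing.assert_allclose(full, simp, atol=1e-4)


class TestConfidenceLikelihood:
    def test_report_density_normalizes(self):
        # density of the observed report integrates to 1 over [0.5, 1]
        df = toy_table(6, seed=1)
        grid = np.linspace(0.5, 1.0, 401)
        for simplified in (True, False):
            dens = []
            for c in grid:
                d = df.assign(conf_report=c)
                dens.append(np.exp(confidence_loglik(d, PARAMS, "flexible",
                                                     simplified)))
            integral = np.trapezoid(np.array(dens), grid, axis=0)
            np.testing.assert_allclose(integral, 1.0, atol=2e-3)

    def test_flat_prior_reduction(self):
        # with a flat prior the predicted confidence is the target-only
        # posterior, mapped to the report scale
        df = toy_table(30, seed=2)
        mu = predicted_confidence(df, PARAMS, "flat_prior",
                                  use_simplification=True)
        data = ParticipantData.from_table(df)
        like = norm.cdf(data.r_target_simp / PARAMS["b"])
        expected = np.clip(np.where(data.target_choice > 0, like, 1 - like),
                           0.5, 1.0)
        np.testing.assert_allclose(mu, expected, atol=1e-9)

    def test_simplification_underestimates_confidence(self, small_cohort):
        # mean-strength substitution places internal samples on the correct
        # side, predicting systematically lower confidence than the full model
        _, trials = small_cohort
        sub = trials[trials.participant == "sim001"]
        full = predicted_confidence(sub, PARAMS, "flexible",
                                    use_simplification=False)
        simp = predicted_confidence(sub, PARAMS, "flexible",
                                    use_simplification=True)
        assert simp.mean() < full.mean()

    def test_zero_report_noise_rejected(self):
        with pytest.raises(Exception):
            confidence_loglik(toy_table(), {**PARAMS, "report_noise_sd": 0.0},
                              "flexible", True)


class TestIndividualFit:
    def test_recovery_within_posterior_uncertainty(self):
        # single observer, 720 trials, full-likelihood posterior
        from priorconf.observer import ObserverParams
        true = ObserverParams(w_choice=2.4, w_conf=2.0, b=1.0, sigma=0.1,
                              report_noise_sd=0.1)
        trials = simulate_and_normalize(
            [true], ExperimentDesign(n_participants=1), seed=21)
        cfg = SamplerConfig(n_burn=200, n_steps=300, conf_quad_nodes=10, seed=4)
        fit = fit_individual(trials, "flexible", cfg)
        for name, truth in [("w_choice", 2.4), ("w_conf", 2.0), ("b", 1.0)]:
            row = fit.summaries.set_index("parameter").loc[name]
            assert abs(row["mean"] - truth) < 2.0 * row["sd"] + 0.1, (
                f"{name}: {row['mean']:.2f} vs {truth} (sd {row['sd']:.2f})")

    def test_result_reports_diagnostics(self, small_cohort):
        _, trials = small_cohort
        sub = trials[trials.participant == "sim001"]
        cfg = SamplerConfig(n_burn=40, n_steps=60, conf_quad_nodes=8, seed=0)
        fit = fit_individual(sub, "optimal", cfg)
        assert {"b", "report_noise_sd"} <= set(fit.draws)
        assert "rhat" in fit.summaries.columns
        assert isinstance(fit.converged, bool)
        lo = fit.summaries["ci89_low"].to_numpy()
        hi = fit.summaries["ci89_high"].to_numpy()
        assert (lo <= hi).all()


class TestHierarchicalFit:
    def test_group_recovery_from_matching_process(self):
        # resample responses from the simplified generative process, then
        # check the group posterior covers the cohort's log-scale location
        params = make_cohort_params(8, {"w_choice": 2.17, "w_conf": 1.27,
                                        "b": 2.18}, seed=3)
        trials = simulate_and_normalize(
            params, ExperimentDesign(n_participants=8, sessions=1,
                                     blocks_per_session=10), seed=3)
        pmap = {f"sim{i + 1:03d}": {"w_choice": p.w_choice,
                                    "w_conf": p.w_conf, "b": p.b,
                                    "report_noise_sd": 0.1}
                for i, p in enumerate(params)}
        trials = resample_from_simplified(trials, pmap, seed=11)
        fit = fit_hierarchical(trials, "flexible",
                               SamplerConfig(n_burn=400, n_steps=700, seed=0))
        summ = fit.summaries.set_index("parameter")
        for name, attr in [("w_choice_group", "w_choice"),
                           ("w_conf_group", "w_conf"), ("b_group", "b")]:
            truth = float(np.exp(np.mean([np.log(getattr(p, attr))
                                          for p in params])))
            row = summ.loc[name]
            tol = 2.0 * np.sqrt(row["sd"] ** 2 + row["mcse"] ** 2)
            assert abs(row["mean"] - truth) < tol + 0.05, (name, row["mean"], truth)
        sd_row = summ.loc["report_noise_sd"]
        assert sd_row["mean"] == pytest.approx(0.1, abs=0.02)

    def test_degenerate_hierarchy_shrinks_group_sd(self):
        # identical true parameters for everyone: group SDs concentrate near 0
        # (posterior piles at small values with a thin upper tail)
        params = make_cohort_params(6, {"w_choice": 2.0, "w_conf": 1.3,
                                        "b": 2.0}, between_sd_log=0.0, seed=9)
        trials = simulate_and_normalize(
            params, ExperimentDesign(n_participants=6, sessions=1,
                                     blocks_per_session=10), seed=9)
        pmap = {f"sim{i + 1:03d}": {"w_choice": 2.0, "w_conf": 1.3, "b": 2.0,
                                    "report_noise_sd": 0.1}
                for i in range(6)}
        trials = resample_from_simplified(trials, pmap, seed=10)
        fit = fit_hierarchical(trials, "flexible",
                               SamplerConfig(n_burn=400, n_steps=600, seed=1))
        summ = fit.summaries.set_index("parameter")
        for name in ("tau_w_choice", "tau_w_conf", "tau_b"):
            assert float(np.median(fit.draws[name])) < 0.3
            assert summ.loc[name, "ci89_low"] < 0.1

    def test_difference_distribution_available(self, small_cohort):
        _, trials = small_cohort
        fit = fit_hierarchical(trials, "flexible",
                               SamplerConfig(n_burn=60, n_steps=80, seed=2))
        d = fit.draws["w_choice_minus_w_conf"]
        np.testing.assert_allclose(
            d, fit.draws["w_choice_group"] - fit.draws["w_conf_group"])
        lo, hi = np.quantile(d, [0.055, 0.945])
        assert lo < hi

    def test_needs_two_participants(self, small_cohort):
        _, trials = small_cohort
        one = trials[trials.participant == "sim001"]
        with pytest.raises(Exception):
            fit_hierarchical(one, "flexible")


class TestOutlierExclusion:
    def _estimates(self, w_conf_last=1.3):
        rng = np.random.default_rng(0)
        n = 10
        df = pd.DataFrame({
            "participant": [f"p{i:02d}" for i in range(n)],
            "w_choice": 2.0 + 0.1 * rng.standard_normal(n),
            "w_conf": 1.3 + 0.1 * rng.standard_normal(n),
            "b": 2.0 + 0.1 * rng.standard_normal(n),
        })
        df.loc[n - 1, "w_conf"] = w_conf_last
        return df

    def test_homogeneous_cohort_keeps_everyone(self):
        retained, log = exclude_outliers(self._estimates())
        assert len(retained) == 10 and log == []

    def test_planted_outlier_excluded(self):
        df = self._estimates(w_conf_last=1.3)
        sd = df["w_conf"].std(ddof=1)
        df.loc[9, "w_conf"] = df["w_conf"].mean() + 30 * sd
        retained, log = exclude_outliers(df)
        assert "p09" not in retained and len(retained) == 9
        assert log[0]["participant"] == "p09"

    def test_order_invariant(self):
        df = self._estimates()
        df.loc[9, "w_conf"] = 60.0
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        r1, _ = exclude_outliers(df)
        r2, _ = exclude_outliers(shuffled)
        assert sorted(r1) == sorted(r2)
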