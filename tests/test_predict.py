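"""Bayesian individualized prediction: conjugacy, shrinkage, calibration."""

import math

import numpy as np
import pytest

from pvtsim import (PosteriorModel, ProtocolConfig, SessionSlot,
                    default_prior, design_row, forecast, run_post_hoc,
                    simulate_study, tsd_schedule, update_posterior)
from pvtsim.predict import simulate_observations, statistic_value
from pvtsim.stats import summarize


def _slots(n=10, step=2.0, wake_clock=8.0):
    return [SessionSlot(k * step, (wake_clock + k * step) % 24.0)
            for k in range(n)]


def _observations(prior, slots, theta, seed):
    rng = np.random.default_rng(seed)
    y = simulate_observations(theta, slots, math.sqrt(prior.noise_var), rng,
                              tau_h=prior.tau_h)
    return list(zip(slots, y))


class TestDesignRow:
    def test_homeostatic_feature_zero_at_wake(self):
        row = design_row(0.0, 13.0)
        assert row[0] == 1.0 and row[1] == 0.0

    def test_periodic_in_clock(self):
        np.testing.assert_allclose(design_row(10.0, 3.0),
                                   design_row(10.0, 27.0), atol=1e-12)

    def test_matches_direct_basis_evaluation(self):
        t, c, tau = 7.3, 19.4, 16.0
        w = 2 * math.pi * c / 24.0
        expected = [1.0, 1.0 - math.exp(-t / tau), math.cos(w), math.sin(w)]
        np.testing.assert_allclose(design_row(t, c, tau), expected,
                                   atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            design_row(-1.0, 8.0)


class TestUpdatePosterior:
    def test_zero_observations_returns_prior_unchanged(self):
        prior = default_prior()
        post = update_posterior(prior, [])
        np.testing.assert_array_equal(post.theta_mean, prior.theta_mean)
        np.testing.assert_array_equal(post.theta_cov, prior.theta_cov)
        assert post.n_sessions_used == 0
        assert post.prior_weight == pytest.approx(1.0)

    def test_incremental_equals_batch(self):
        prior = default_prior()
        obs = _observations(prior, _slots(12), [1.2, 3.5, 0.7, -0.4], seed=8)
        batch = update_posterior(prior, obs)
        model = prior
        for pair in obs:
            model = update_posterior(model, [pair])
        np.testing.assert_allclose(model.theta_mean, batch.theta_mean,
                                   atol=1e-8)
        np.testing.assert_allclose(model.theta_cov, batch.theta_cov,
                                   atol=1e-8)
        assert model.n_sessions_used == batch.n_sessions_used == 12

    def test_prior_weight_non_increasing_and_trace_shrinks(self):
        prior = default_prior()
        obs = _observations(prior, _slots(15), [1.0, 4.0, 0.5, 0.5], seed=3)
        weights, traces = [], []
        model = prior
        for pair in obs:
            model = update_posterior(model, [pair])
            weights.append(model.prior_weight)
            traces.append(float(np.trace(model.theta_cov)))
        assert all(b <= a for a, b in zip(weights, weights[1:]))
        assert all(b < a for a, b in zip(traces, traces[1:]))
        assert weights[0] < 1.0

    def test_posterior_cov_below_prior_in_loewner_order(self):
        prior = default_prior()
        obs = _observations(prior, _slots(8), [1.0, 4.0, 0.0, 0.0], seed=1)
        post = update_posterior(prior, obs)
        gap_eigs = np.linalg.eigvalsh(prior.theta_cov - post.theta_cov)
        assert np.all(gap_eigs >= -1e-10)

    def test_shift_equivariance(self):
        """Adding a constant to every observation shifts the intercept and
        all point forecasts by that constant."""
        prior = default_prior()
        slots = _slots(10)
        obs = _observations(prior, slots, [1.0, 4.0, 0.3, -0.2], seed=5)
        shifted = [(s, y + 2.5) for s, y in obs]
        a = update_posterior(prior, obs)
        # shift the prior intercept too: equivariance of the full map
        from dataclasses import replace
        prior_b = replace(prior,
                          theta_mean=prior.theta_mean + [2.5, 0, 0, 0])
        b = update_posterior(prior_b, shifted)
        future = _slots(4, step=3.0)
        fa = forecast(a, future)
        fb = forecast(b, future)
        np.testing.assert_allclose(fb.point, fa.point + 2.5, atol=1e-8)
        assert b.theta_mean[0] == pytest.approx(a.theta_mean[0] + 2.5)


class TestForecast:
    def test_interval_brackets_point(self):
        prior = default_prior()
        post = update_posterior(
            prior, _observations(prior, _slots(6), [1, 4, 0, 0], seed=2))
        fc = forecast(post, _slots(8, step=3.0))
        assert np.all(fc.pi_low <= fc.point) and np.all(fc.point <= fc.pi_high)
        assert np.all(np.diff(fc.times_h) > 0)

    def test_degenerate_zero_variance_collapses_interval(self):
        post = PosteriorModel(theta_mean=np.array([1.0, 4.0, 0.0, 0.0]),
                              theta_cov=np.zeros((4, 4)), noise_var=0.0,
                              tau_h=16.0, statistic="minor_lapses_sqrt",
                              n_sessions_used=99, prior_cov_trace=7.0)
        fc = forecast(post, _slots(5))
        np.testing.assert_array_equal(fc.pi_low, fc.point)
        np.testing.assert_array_equal(fc.pi_high, fc.point)

    def test_horizon_beyond_24h_refused_unless_overridden(self):
        prior = default_prior()
        far = [SessionSlot(40.0, 0.0)]
        with pytest.raises(ValueError, match="horizon"):
            forecast(prior, far, now_awake_h=10.0)
        fc = forecast(prior, far, now_awake_h=10.0, allow_beyond_24h=True)
        assert fc.point.shape == (1,)

    def test_prediction_interval_coverage_on_held_out_sessions(self):
        """95% intervals should cover 92-98% of 500 held-out observations
        drawn from the model with prior-distributed subjects."""
        prior = default_prior()
        rng = np.random.default_rng(77)
        chol = np.linalg.cholesky(prior.theta_cov)
        train = _slots(10)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            theta = prior.theta_mean + chol @ rng.standard_normal(4)
            obs = list(zip(train, simulate_observations(
                theta, train, math.sqrt(prior.noise_var), rng)))
            post = update_posterior(prior, obs)
            held = [SessionSlot(24.0, 8.0)]
            y_new = simulate_observations(
                theta, held, math.sqrt(prior.noise_var), rng)[0]
            fc = forecast(post, held)
            hits += fc.pi_low[0] <= y_new <= fc.pi_high[0]
        assert 0.92 <= hits / n_rep <= 0.98


class TestRunPostHoc:
    def test_single_session_study_gives_one_step(
            self, tsd_subject, gaming_device, config):
        study = simulate_study(tsd_subject, tsd_schedule(1.0, 2.0), config,
                               gaming_device, seed=9)
        steps = run_post_hoc(study, default_prior())
        assert len(steps) == 1
        assert steps[0].posterior.n_sessions_used == 1

    def test_statistic_extraction_matches_summaries(
            self, tsd_subject, gaming_device, config):
        study = simulate_study(tsd_subject, tsd_schedule(8.0, 2.0), config,
                               gaming_device, seed=10)
        st = summarize(study[2])
        assert statistic_value(st, "minor_lapses_sqrt") == pytest.approx(
            math.sqrt(st.minor_lapses))
        assert statistic_value(st, "mean_rt") == st.mean_rt_ms

    def test_unordered_sessions_rejected(self, tsd_subject, gaming_device,
                                         config):
        study = simulate_study(tsd_subject, tsd_schedule(6.0, 2.0), config,
                               gaming_device, seed=2)
        with pytest.raises(ValueError):
            run_post_hoc(list(reversed(study)), default_prior())

    def test_parameter_recovery_after_43_session_tsd_study(self):
        """Posterior mean lands within 3 posterior SDs of the generating
        amplitudes after a full 85-h TSD schedule of observations."""
        prior = default_prior()
        theta_true = np.array([1.3, 3.2, 0.6, -0.8])
        slots = [SessionSlot(s.t_awake_h, s.clock_h)
                 for s in tsd_schedule(85.0, 2.0)]
        obs = _observations(prior, slots, theta_true, seed=14)
        post = update_posterior(prior, obs)
        sds = np.sqrt(np.diag(post.theta_cov))
        assert np.all(np.abs(post.theta_mean - theta_true) <= 3 * sds)

    def test_prediction_error_shrinks_with_learning(
            self, tsd_subject, gaming_device):
        """Mean absolute 2-h-ahead error is smaller after 40 sessions than
        after 3 (averaged over seeds): individualization beats the prior."""
        cfg = ProtocolConfig(session_duration_s=300.0)
        prior = default_prior()
        errs_early, errs_late = [], []
        for seed in range(50):
            study = simulate_study(tsd_subject, tsd_schedule(85.0, 2.0),
                                   cfg, gaming_device, seed=seed)
            y = [statistic_value(summarize(s), "minor_lapses_sqrt")
                 for s in study]
            steps = run_post_hoc(study, prior, horizon_h=2.0, step_h=2.0)
            for k, errs in ((2, errs_early), (39, errs_late)):
                pred = steps[k].forecast.point[0]  # 2 h ahead of session k+1
                errs.append(abs(pred - y[k + 1]))
        assert np.mean(errs_late) <= np.mean(errs_early)
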