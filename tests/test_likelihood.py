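"""Likelihood tests: closed-form collapses, simulation oracles, normalization."""

import numpy as np
import pytest
from scipy import stats

from stoptf import (
    ExGaussParams,
    LikelihoodSettings,
    SSDSchedule,
    SubjectParams,
    exgauss_sample,
    inhibit_prob,
    loglik_go,
    loglik_inhibit,
    loglik_signal_respond,
    respond_prob,
    simulate_dataset,
    total_loglik,
)
from stoptf.distributions import exgauss_logpdf
from stoptf.likelihood import signal_respond_logdensity, split_trials


def _sp(go, stop, ptf):
    return SubjectParams(go=go, stop=stop, ptf=ptf)


class TestGoLoglik:
    def test_empty_is_zero(self, go_params):
        assert loglik_go([], go_params) == 0.0

    def test_single_rt_is_logpdf(self, go_params):
        assert loglik_go([512.0], go_params) == pytest.approx(
            float(exgauss_logpdf(512.0, go_params)), abs=1e-12
        )

    def test_matches_per_point_sum(self, go_params, rng):
        rts = exgauss_sample(1000, go_params, rng)
        oracle = sum(float(exgauss_logpdf(t, go_params)) for t in rts)
        assert loglik_go(rts, go_params) == pytest.approx(oracle, abs=1e-8)


class TestSignalRespond:
    def test_ptf_one_collapses_to_go(self, go_params, stop_params, rng):
        rts = exgauss_sample(200, go_params, rng)
        ssds = np.full(200, 250.0)
        sp = _sp(go_params, stop_params, 1.0)
        assert loglik_signal_respond(rts, ssds, sp) == pytest.approx(
            loglik_go(rts, go_params), abs=1e-9
        )

    def test_ptf_zero_is_censored_form(self, go_params, stop_params, rng):
        # independent censored-likelihood implementation via scipy.exponnorm
        rts = exgauss_sample(500, go_params, rng)
        ssds = np.full(500, 250.0)
        sp = _sp(go_params, stop_params, 0.0)
        k = stop_params.tau / stop_params.sigma
        surv = stats.exponnorm.sf(rts - ssds, k, loc=stop_params.mu,
                                  scale=stop_params.sigma)
        kg = go_params.tau / go_params.sigma
        dens = stats.exponnorm.pdf(rts, kg, loc=go_params.mu, scale=go_params.sigma)
        oracle = float(np.sum(np.log(surv * dens)))
        assert loglik_signal_respond(rts, ssds, sp) == pytest.approx(oracle, rel=1e-9)

    def test_density_matches_race_simulation(self, subject_ptf10):
        # histogram of simulated signal-respond RTs scaled by P(respond)
        # is the defective density the likelihood assigns
        ssd = 250.0
        n = 10_000_000
        g = np.random.default_rng(123)
        go = exgauss_sample(n, subject_ptf10.go, g)
        trig = g.random(n) >= subject_ptf10.ptf
        ssrt = exgauss_sample(n, subject_ptf10.stop, g)
        resp = ~trig | (go < ssd + ssrt)
        sr = go[resp]
        edges = np.linspace(300, 700, 21)
        hist, _ = np.histogram(sr, bins=edges)
        width = edges[1] - edges[0]
        centers = 0.5 * (edges[:-1] + edges[1:])
        emp_dens = hist / n / width  # defective density (mass = P(respond))
        model = np.exp(signal_respond_logdensity(centers, np.full_like(centers, ssd),
                                                 subject_ptf10))
        se = np.sqrt(np.maximum(hist, 1)) / n / width
        # bin-averaging bias is second order; allow 4 SE plus a small slack
        assert np.all(np.abs(emp_dens - model) < 4 * se + 2e-6)

    def test_mismatched_lengths_raise(self, subject_ptf10):
        with pytest.raises(ValueError):
            loglik_signal_respond([400.0, 410.0], [250.0], subject_ptf10)


class TestInhibit:
    def test_very_early_ssd_reaches_trigger_ceiling(self, go_params, stop_params):
        # when the stop process always wins the race, the only way to respond
        # is a trigger failure: per-trial inhibition probability -> 1 - ptf
        sp = _sp(go_params, stop_params, 0.1)
        ssds = np.full(7, -1e9)
        assert loglik_inhibit(ssds, sp) == pytest.approx(7 * np.log(0.9), abs=1e-9)

    def test_very_late_ssd_floored(self, subject_ptf10):
        s = LikelihoodSettings()
        val = loglik_inhibit([1e9], subject_ptf10, s)
        assert val == pytest.approx(np.log(s.floor))

    @pytest.mark.parametrize("ssd", [100.0, 250.0, 400.0])
    def test_probability_matches_simulation(self, subject_ptf10, ssd):
        n = 1_000_000
        g = np.random.default_rng(321)
        go = exgauss_sample(n, subject_ptf10.go, g)
        trig = g.random(n) >= subject_ptf10.ptf
        ssrt = exgauss_sample(n, subject_ptf10.stop, g)
        inhibited = trig & (go >= ssd + ssrt)
        p_model = float(inhibit_prob(ssd, subject_ptf10))
        se = np.sqrt(p_model * (1 - p_model) / n)
        assert abs(inhibited.mean() - p_model) < 3 * se

    def test_adaptive_and_fixed_quadrature_agree(self, subject_ptf10):
        ssds = np.array([0.0, 150.0, 300.0, 500.0])
        fast = inhibit_prob(ssds, subject_ptf10)
        slow = inhibit_prob(ssds, subject_ptf10, LikelihoodSettings(method="adaptive"))
        assert np.allclose(fast, slow, atol=1e-9)


class TestTotalLoglik:
    def test_additivity(self, subject_ptf10, staircase):
        df = simulate_dataset(subject_ptf10, 300, 150, staircase, seed=11)
        go_rts, sr_rts, sr_ssds, inh_ssds = split_trials(df)
        total = total_loglik(df, subject_ptf10)
        parts = (
            loglik_go(go_rts, subject_ptf10.go)
            + loglik_signal_respond(sr_rts, sr_ssds, subject_ptf10)
            + loglik_inhibit(inh_ssds, subject_ptf10)
        )
        assert total == pytest.approx(parts, abs=1e-9)

    def test_invariant_under_reordering(self, subject_ptf10, staircase):
        df = simulate_dataset(subject_ptf10, 200, 100, staircase, seed=12)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert total_loglik(df, subject_ptf10) == pytest.approx(
            total_loglik(shuffled, subject_ptf10), abs=1e-9
        )

    def test_signal_respond_mass_plus_inhibit_prob_is_one(self, subject_ptf10):
        # the inhibition integral is the normalising constant of the defective
        # signal-respond density: together they form a proper measure
        from scipy import integrate

        for ssd in (100.0, 250.0, 400.0):
            mass, _ = integrate.quad(
                lambda t: float(
                    np.exp(signal_respond_logdensity(t, ssd, subject_ptf10))
                ),
                -1500, 4000, limit=400,
            )
            total = mass + float(inhibit_prob(ssd, subject_ptf10))
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_higher_ptf_likes_early_responses_better(self, go_params, stop_params):
        # a dataset with many early-SSD responses is better explained by
        # a larger trigger-failure probability
        sched = SSDSchedule(mode="fixed", fixed_levels=[-200.0])
        sp_gen = _sp(go_params, stop_params, 0.4)
        df = simulate_dataset(sp_gen, 100, 400, sched, seed=13)
        lo = total_loglik(df, _sp(go_params, stop_params, 0.05))
        hi = total_loglik(df, _sp(go_params, stop_params, 0.4))
        assert hi > lo

    def test_ptf_zero_matches_independent_censored_model(self, go_params, stop_params,
                                                         staircase):
        # the standard (no-trigger-failure) model is the exact ptf = 0 slice
        sp0 = _sp(go_params, stop_params, 0.0)
        df = simulate_dataset(sp0, 200, 200, staircase, seed=14)
        go_rts, sr_rts, sr_ssds, inh_ssds = split_trials(df)

        kg = go_params.tau / go_params.sigma
        ks = stop_params.tau / stop_params.sigma
        go_d = stats.exponnorm(kg, loc=go_params.mu, scale=go_params.sigma)
        stop_d = stats.exponnorm(ks, loc=stop_params.mu, scale=stop_params.sigma)

        from scipy import integrate

        oracle = float(np.sum(go_d.logpdf(go_rts)))
        oracle += float(np.sum(np.log(stop_d.sf(sr_rts - sr_ssds))
                               + go_d.logpdf(sr_rts)))
        for ssd in inh_ssds:
            val, _ = integrate.quad(
                lambda t: go_d.sf(t) * stop_d.pdf(t - ssd), -500 + ssd, 3000 + ssd,
                limit=400,
            )
            oracle += np.log(val)
        assert total_loglik(df, sp0) == pytest.approx(oracle, rel=1e-7)
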