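"""Bayesian fitting, model weights and goodness of fit."""

import math

import numpy as np
import pytest
from scipy import stats

from ca3mod.inference import (compare_models, default_priors, fit_mh,
                              information_criteria, information_weights,
                              log_likelihood, metropolis,
                              posterior_covariance, posterior_predictive_p)
from ca3mod.stp import AmplitudeTrain, ModelSpec, STPParams, StimulusTrain
from ca3mod.synth import condition_spec, generate_dataset

F2 = ModelSpec.preset("f2")
EPSC = STPParams(g_max=6.6, tau_f=3.3, f0=0.3, a=0.15)


class TestLogLikelihood:
    def test_matches_hand_coded_density_sum(self):
        stim = StimulusTrain([0.0, 0.1, 0.5, 2.0, 7.0])
        from ca3mod.stp import iterate_stp
        amps = 6.6 * iterate_stp(EPSC, F2, stim).amplitudes * 80.0
        rng = np.random.default_rng(1)
        y = amps + rng.normal(0, 3.0, amps.size)
        ll = log_likelihood(EPSC, F2, stim, AmplitudeTrain(stim, np.abs(y)))
        sd = np.sqrt(0.5 * amps)
        expected = stats.norm.logpdf(np.abs(y), amps, sd).sum()
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_decreases_with_residual_magnitude(self, protocol, epsc_dataset):
        obs = epsc_dataset.trains[0]
        base = log_likelihood(EPSC, F2, protocol, obs)
        mean = epsc_dataset.model_amplitudes
        doubled = AmplitudeTrain(protocol, np.abs(mean + 2 * (obs.amplitudes - mean)))
        assert log_likelihood(EPSC, F2, protocol, doubled) < base

    def test_maximal_at_zero_residuals(self, protocol, epsc_dataset):
        mean = epsc_dataset.model_amplitudes
        exact = AmplitudeTrain(protocol, mean)
        ll = log_likelihood(EPSC, F2, protocol, exact)
        sd = np.sqrt(0.5 * mean)
        assert ll == pytest.approx(
            np.sum(-np.log(sd) - 0.5 * math.log(2 * math.pi)), rel=1e-10)


class TestMetropolisHastings:
    def test_empty_data_recovers_the_prior(self, protocol):
        fit = fit_mh(F2, protocol, np.empty(0), n_steps=30_000, n_burn=5_000,
                     thin=30, seed=2)
        g = fit.chain[:, fit.param_names.index("g_max")]
        f0 = fit.chain[:, fit.param_names.index("f0")]
        tf = fit.chain[:, fit.param_names.index("tau_f")]
        assert stats.kstest(g, "expon", args=(0, 10.0)).pvalue > 0.01
        assert stats.kstest(f0, "beta", args=(1, 3)).pvalue > 0.01
        assert stats.kstest(tf, "uniform", args=(0.01, 19.99)).pvalue > 0.01

    def test_conjugate_toy_matches_analytic_posterior(self):
        # unknown normal mean, known sd=2, prior N(0, 5^2), 50 points
        rng = np.random.default_rng(3)
        y = rng.normal(1.5, 2.0, 50)
        tau0, tau = 1 / 25.0, 50 / 4.0
        post_mean = tau * y.mean() / (tau0 + tau)
        post_sd = 1 / np.sqrt(tau0 + tau)

        def logpdf(m):
            return -0.5 * m ** 2 / 25.0 - np.sum((y - m) ** 2) / 8.0

        chain = metropolis(logpdf, 0.0, 20_000, seed=4, step=0.5)
        thinned = chain[::20]
        mcse = thinned.std() / np.sqrt(thinned.size)
        assert abs(chain.mean() - post_mean) < 3 * mcse + 1e-3
        assert chain.std() == pytest.approx(post_sd, rel=0.1)

    def test_amplitude_scale_recovered(self, f2_fit):
        # g * f0^2 sets the baseline amplitude and is tightly identified
        mp = f2_fit.map_estimate()
        assert mp["g_max"] * mp["f0"] ** 2 == pytest.approx(
            6.6 * 0.3 ** 2, rel=0.15)
        assert 0.2 < f2_fit.acceptance_rate < 0.6

    def test_reports_acceptance_and_reproducible(self, protocol, epsc_dataset):
        a = fit_mh(F2, protocol, epsc_dataset.trains[0], n_steps=2000,
                   n_burn=1000, seed=5)
        b = fit_mh(F2, protocol, epsc_dataset.trains[0], n_steps=2000,
                   n_burn=1000, seed=5)
        assert np.array_equal(a.chain, b.chain)
        assert a.acceptance_rate == b.acceptance_rate


class TestInformationWeights:
    def test_equal_criteria_split_evenly(self):
        w = information_weights({"a": 100.0, "b": 100.0})
        assert w["a"] == pytest.approx(0.5)

    def test_known_delta_triplet(self):
        w = information_weights({"a": 0.0, "b": 2.0, "c": 4.0})
        expected = 1.0 / (1.0 + math.exp(-1.0) + math.exp(-2.0))
        assert w["a"] == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_on_random_values(self):
        rng = np.random.default_rng(6)
        vals = {f"m{i}": rng.uniform(100, 200) for i in range(4)}
        w = information_weights(vals)
        raw = {k: math.exp(-0.5 * abs(v - min(vals.values())))
               for k, v in vals.items()}
        z = sum(raw.values())
        for k in vals:
            assert w[k] == pytest.approx(raw[k] / z, rel=1e-9)
        assert sum(w.values()) == pytest.approx(1.0)

    def test_per_sample_mode_averages_deltas(self):
        # two samples with alternating winners -> symmetric weights
        w = information_weights({"a": [0.0, 2.0], "b": [2.0, 0.0]})
        assert w["a"] == pytest.approx(w["b"])

    def test_comparison_object(self, protocol, epsc_dataset, f2_fit):
        af_fit = fit_mh(ModelSpec.preset("af"), protocol,
                        epsc_dataset.trains[0], n_steps=6000, n_burn=2000,
                        seed=7)
        comp = compare_models({"f2": f2_fit, "af": af_fit})
        assert sum(comp.bic_weights.values()) == pytest.approx(1.0)
        assert sum(comp.aic_weights.values()) == pytest.approx(1.0)
        assert comp.evidence_ratio(comp.best("bic"),
                                   min(comp.bic_weights,
                                       key=comp.bic_weights.get)) >= 1.0
        ic = information_criteria(f2_fit)
        assert ic["bic"] > ic["aic"]  # ln(100) > 2 per parameter


class TestPosteriorPredictive:
    def test_self_consistent_data_near_half(self, protocol, epsc_dataset, f2_fit):
        p = posterior_predictive_p(f2_fit, F2, protocol,
                                   epsc_dataset.trains[0], n_draws=500, seed=8)
        assert 0.2 < p < 0.8

    def test_gross_misfit_detected(self, protocol, epsc_dataset, f2_fit):
        mean = epsc_dataset.model_amplitudes
        shifted = AmplitudeTrain(protocol,
                                 mean + 10 * np.sqrt(0.5 * mean))
        p = posterior_predictive_p(f2_fit, F2, protocol, shifted,
                                   n_draws=200, seed=9)
        assert p < 0.025 or p > 0.975


class TestPosteriorCovariance:
    def test_prior_sampling_uncorrelated(self, protocol):
        fit = fit_mh(F2, protocol, np.empty(0), n_steps=100_000, n_burn=5000,
                     thin=10, seed=10)
        corr = posterior_covariance(fit).to_numpy()
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_symmetric_with_unit_diagonal(self, f2_fit):
        corr = posterior_covariance(f2_fit)
        m = corr.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_conductance_baseline_tradeoff_is_negative(self, f2_fit):
        corr = posterior_covariance(f2_fit)
        assert corr.loc["g_max", "f0"] < 0
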