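"""Tests of featurization, free energy and variational-Laplace inversion."""

import numpy as np
import pytest
from dataclasses import replace

import tcdcm as T
from tcdcm.inversion import laplace_free_energy
from tcdcm.model import ParamSpec


@pytest.fixture(scope="module")
def coarse_csd(params, coarse_freqs):
    """Noise-free self-data on the reduced grid."""
    return T.predict_csd(params.evaluate(), coarse_freqs)


class TestFeaturize:
    def test_length_is_6F(self, coarse_csd, coarse_freqs):
        assert T.featurize(coarse_csd).size == 6 * coarse_freqs.size

    def test_self_residual_is_zero(self, params, coarse_csd, coarse_freqs):
        pred = T.predict_csd(params.evaluate(), coarse_freqs)
        np.testing.assert_array_equal(
            T.featurize(pred) - T.featurize(coarse_csd), 0.0)

    def test_round_trip(self, coarse_csd):
        back = T.defeaturize(T.featurize(coarse_csd), coarse_csd.freqs)
        np.testing.assert_allclose(back.S, coarse_csd.S, atol=1e-300)

    def test_nan_rejected(self, coarse_csd):
        bad = T.SpectralData(coarse_csd.freqs, coarse_csd.S.copy())
        bad.S[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            T.featurize(bad)


class TestFreeEnergy:
    def test_kl_zero_at_prior_with_perfect_prediction(self, params, priors,
                                                      coarse_csd):
        # at lam = mu0 with Sigma = Sigma0 and zero residual, F reduces to
        # the noise normalization alone: the KL term is exactly zero
        h = 1.3
        F = T.free_energy(params.prior_means, coarse_csd, priors, h, params)
        n = 6 * coarse_csd.freqs.size
        assert F == pytest.approx(0.5 * n * (h - np.log(2 * np.pi)), rel=1e-12)

    def test_larger_residual_lowers_f(self, params, priors, coarse_csd):
        h = 0.0
        scaled = [T.SpectralData(coarse_csd.freqs, c * coarse_csd.S)
                  for c in (1.0, 1.01, 1.05)]
        Fs = [T.free_energy(params.prior_means, s, priors, h, params)
              for s in scaled]
        assert Fs[0] > Fs[1] > Fs[2]

    def test_unstable_parameters_get_sentinel(self, params, priors,
                                              coarse_csd):
        # a runaway thalamocortical loop with weakened frontal inhibition:
        # no stationary point exists, so the proposal is rejected outright
        lam = params.lam_from_dict({
            "g_frontal_tp_rl": 5.5, "g_frontal_rl_ss": 2.1,
            "g_frontal_sp_sp": -2.8, "g_frontal_si_sp": -1.7,
            "kappa_frontal_nmda": -2.6})
        F = T.free_energy(lam, coarse_csd, priors, 0.0, params)
        assert F == -1e10

    def test_linear_gaussian_toy_matches_closed_form_evidence(self):
        """For y = a*lam + noise with known precision, F at the analytic
        posterior equals the marginal likelihood exactly."""
        rng = np.random.default_rng(77)
        n = 40
        a = rng.standard_normal(n)
        v0 = 0.5          # prior variance of the single latent
        s = 4.0           # known noise precision
        lam_true = 0.3
        y = a * lam_true + rng.standard_normal(n) / np.sqrt(s)
        # analytic posterior
        Sig = 1.0 / (s * a @ a + 1.0 / v0)
        mu = Sig * s * (a @ y)
        F = laplace_free_energy(
            e=y - a * mu, h=np.log(s), mu_free=np.array([mu]),
            Sigma=np.array([[Sig]]), mu0_free=np.zeros(1),
            var0_free=np.array([v0]), J=a[:, None])
        # closed form: y ~ N(0, v0 a a' + I/s)
        C = v0 * np.outer(a, a) + np.eye(n) / s
        sign, logdet = np.linalg.slogdet(C)
        log_ev = -0.5 * (y @ np.linalg.solve(C, y) + logdet
                         + n * np.log(2 * np.pi))
        assert F == pytest.approx(log_ev, abs=1e-6)


@pytest.fixture(scope="module")
def self_fit(params, priors, coarse_csd):
    return T.invert(coarse_csd, priors, params=params)


class TestInvert:
    def test_noise_free_self_inversion(self, self_fit, params, coarse_csd):
        assert self_fit.variance_explained >= 99.0
        assert np.max(np.abs(self_fit.mu - params.prior_means)) < 0.05

    def test_free_energy_trace_non_decreasing(self, self_fit):
        assert np.all(np.diff(self_fit.F_trace) >= 0)

    def test_posterior_covariance_psd(self, self_fit):
        ev = np.linalg.eigvalsh(self_fit.Sigma)
        assert ev.min() > -1e-10 * ev.max()

    def test_determinism(self, params, priors, coarse_csd, self_fit):
        res2 = T.invert(coarse_csd, priors, params=params)
        np.testing.assert_array_equal(self_fit.mu, res2.mu)
        np.testing.assert_array_equal(self_fit.F_trace, res2.F_trace)

    def test_recovers_planted_forward_gain_direction(self, params, priors,
                                                     coarse_freqs, self_fit):
        """+0.3 planted on the forward AMPA log-gain must raise its
        posterior relative to the self-inversion baseline in >= 9/10
        noisy datasets."""
        baseline = self_fit.posterior("ext_ampa_fwd")
        lam = params.lam_from_dict({"ext_ampa_fwd": 0.3})
        clean = T.predict_csd(params.evaluate(lam), coarse_freqs)
        wins = 0
        for seed in range(10):
            data = T.add_observation_noise(clean, 0.05,
                                           np.random.default_rng(100 + seed))
            res = T.invert(data, priors, params=params)
            wins += res.posterior("ext_ampa_fwd") > baseline
        assert wins >= 9

    def test_irrelevant_parameter_cannot_buy_evidence(self, params, priors,
                                                      coarse_csd, self_fit):
        """A free latent with no effect on the forward map must not raise F
        by more than 1e-3 on noise-free self-data (complexity penalty)."""
        specs = params.specs + (ParamSpec("unused_dummy", 1.0, 1.0 / 8.0),)
        params2 = T.TCMParameters(nodes=params.nodes, specs=specs,
                                  constants=dict(params.constants))
        priors2 = T.PriorSpec.from_model(params2)
        free = priors.free
        # same posterior state, one extra (inert, at its prior) latent
        mu2 = np.append(self_fit.mu, 0.0)
        k = int(free.sum())
        Sigma2 = np.zeros((k + 1, k + 1))
        Sigma2[:k, :k] = self_fit.Sigma
        Sigma2[k, k] = 1.0 / 8.0
        F1 = T.free_energy(self_fit.mu, coarse_csd, priors, self_fit.h,
                           params, Sigma=self_fit.Sigma)
        F2 = T.free_energy(mu2, coarse_csd, priors2, self_fit.h, params2,
                           Sigma=Sigma2)
        assert F2 <= F1 + 1e-3

    def test_variance_explained_definitions(self, coarse_csd):
        assert T.variance_explained(coarse_csd, coarse_csd) == 100.0
        f = T.featurize(coarse_csd)
        const = T.defeaturize(np.full_like(f, f.mean()), coarse_csd.freqs)
        assert T.variance_explained(const, coarse_csd) == pytest.approx(0.0,
                                                                        abs=1e-9)
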