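"""Covariance model, Wishart likelihood, and priors."""

import numpy as np
import pytest
from scipy import stats

from spatialadmix import (AllelicCovariance, LayerParams, ModelParams,
                          NotPositiveDefiniteError, PriorSettings,
                          admixed_covariance, layer_covariance, log_prior,
                          wishart_loglik)
from spatialadmix.covmodel import WishartLikelihood


def _k1_params(n, alpha0=0.5, alphaD=1.0, alpha2=1.0, phi=0.1, gamma=0.0,
               eta=0.0, spatial=True):
    return ModelParams(layers=[LayerParams(alpha0, alphaD, alpha2, phi)],
                       w=np.ones((n, 1)), gamma=gamma,
                       eta=np.full(n, float(eta)), spatial=spatial)


class TestLayerCovariance:
    def test_zero_distance_gives_alpha0_plus_phi(self):
        lp = LayerParams(0.7, 1.3, 0.9, 0.2)
        g = layer_covariance(lp, np.zeros((2, 2)))
        assert g[0, 1] == pytest.approx(0.9)

    def test_large_distance_decays_to_phi(self):
        lp = LayerParams(1.0, 1.0, 1.0, 0.2)
        g = layer_covariance(lp, np.array([[0.0, 60.0], [60.0, 0.0]]))
        assert g[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_closed_form_value(self):
        lp = LayerParams(1.0, 0.5, 1.0, 0.2)
        g = layer_covariance(lp, np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert g[0, 1] == pytest.approx(np.exp(-1.0) + 0.2)

    def test_monotone_nonincreasing_in_distance(self):
        lp = LayerParams(0.8, 1.7, 1.4, 0.05)
        d = np.linspace(0, 5, 40).reshape(1, -1)
        g = layer_covariance(lp, d).ravel()
        assert np.all(np.diff(g) <= 1e-15)

    def test_alpha0_zero_is_constant(self):
        lp = LayerParams(0.0, 1.0, 1.0, 0.3)
        d = np.abs(np.random.default_rng(0).normal(size=(4, 4)))
        np.fill_diagonal(d, 0)
        g = layer_covariance(lp, (d + d.T) / 2)
        assert np.all(g == 0.3)

    def test_alpha2_domain(self):
        with pytest.raises(ValueError):
            LayerParams(1.0, 1.0, 2.5, 0.1)


class TestAdmixedCovariance:
    def test_single_layer_full_ancestry_equals_kernel(self, grid_distances):
        mp = _k1_params(grid_distances.n_samples)
        om = admixed_covariance(mp, grid_distances).omega
        np.testing.assert_allclose(om, layer_covariance(mp.layers[0],
                                                        grid_distances))

    def test_hand_evaluated_mixture_entry(self):
        # K=2: w1=(1,0), w2=(.5,.5), gamma=.1; G1_12=.4, G2_12=.3
        # -> omega_12 = .1 + 1*.5*.4 + 0*.5*.3 = .3
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        l1 = LayerParams(0.4 - 0.1, 1e-9, 1.0, 0.1)   # G1 ~ .3+.1=.4 at d=1
        l2 = LayerParams(0.3 - 0.05, 1e-9, 1.0, 0.05)  # G2 ~ .3
        mp = ModelParams(layers=[l1, l2], w=np.array([[1, 0], [0.5, 0.5]]),
                         gamma=0.1, eta=np.zeros(2))
        om = admixed_covariance(mp, d, check_pd=False).omega
        assert om[0, 1] == pytest.approx(0.3, abs=1e-6)

    def test_eta_touches_only_the_diagonal(self, grid_distances):
        n = grid_distances.n_samples
        base = _k1_params(n, eta=0.0)
        eta = np.zeros(n)
        eta[0] = 0.2
        bumped = ModelParams(base.layers, base.w, base.gamma, eta)
        om0 = admixed_covariance(base, grid_distances).omega
        om1 = admixed_covariance(bumped, grid_distances).omega
        diff = om1 - om0
        assert diff[0, 0] == pytest.approx(0.2)
        diff[0, 0] = 0.0
        assert np.all(diff == 0.0)

    def test_zero_weight_layer_is_inert(self, grid_distances):
        n = grid_distances.n_samples
        rng = np.random.default_rng(1)
        w1 = rng.dirichlet([1, 1], size=n)
        w2 = np.column_stack([w1, np.zeros(n)])
        layers = [LayerParams(0.5, 1.0, 1.0, 0.1),
                  LayerParams(0.3, 2.0, 0.7, 0.05)]
        extra = LayerParams(0.9, 0.5, 1.5, 0.4)
        mp2 = ModelParams(layers, w1, 0.05, np.full(n, 0.01))
        mp3 = ModelParams(layers + [extra], w2, 0.05, np.full(n, 0.01))
        np.testing.assert_allclose(
            admixed_covariance(mp2, grid_distances).omega,
            admixed_covariance(mp3, grid_distances).omega)

    def test_singular_covariance_is_flagged_with_eigenvalue(self):
        # all variance components zero -> omega = 0, not positive definite
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        mp = ModelParams([LayerParams(0.0, 1.0, 1.0, 0.0)],
                         np.ones((2, 1)), 0.0, np.zeros(2))
        with pytest.raises(NotPositiveDefiniteError) as exc:
            admixed_covariance(mp, d)
        assert exc.value.smallest_eigenvalue is not None

    def test_nonspatial_requires_alpha0_zero(self):
        with pytest.raises(ValueError):
            ModelParams([LayerParams(0.1, 1.0, 1.0, 0.1)], np.ones((2, 1)),
                        0.0, np.zeros(2), spatial=False)


class TestWishartLoglik:
    def _obs(self, n, L, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, L)) * 0.1
        om = x @ x.T / L
        np.fill_diagonal(om, 0.25)
        return AllelicCovariance(om, L)

    def test_scalar_case_reduces_to_scaled_chi_square(self):
        # N=1: L*omega_hat ~ omega * chi2(L); the Wishart log-density equals
        # the chi-square density with the change of variables
        L = 50
        obs = AllelicCovariance(np.array([[0.25]]), L)
        omega = 0.21
        a = 0.25 * L
        expected = stats.chi2.logpdf(a / omega, df=L) - np.log(omega)
        got = wishart_loglik(obs, np.array([[omega]]))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_scipy_oracle_n2(self):
        obs = self._obs(2, 100)
        omega = np.array([[0.26, 0.02], [0.02, 0.24]])
        mine = wishart_loglik(obs, omega)
        oracle = stats.wishart.logpdf(obs.omega_hat * 100, df=100,
                                      scale=omega)
        assert mine == pytest.approx(oracle, abs=1e-8)

    def test_maximized_at_observed_covariance(self):
        obs = self._obs(4, 200, seed=3)
        wl = WishartLikelihood(obs)
        at_mle = wl.loglik(obs.omega_hat)
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = rng.normal(scale=0.02, size=(4, 4))
            perturbed = obs.omega_hat + (p + p.T) / 2
            perturbed = perturbed + 4 * 0.08 * np.eye(4)  # keep PD
            assert wl.loglik(perturbed) <= at_mle

    def test_non_pd_omega_raises_with_eigenvalue(self):
        obs = self._obs(2, 100)
        bad = np.array([[0.25, 0.3], [0.3, 0.25]])
        with pytest.raises(NotPositiveDefiniteError) as exc:
            wishart_loglik(obs, bad)
        assert exc.value.smallest_eigenvalue < 0

    def test_non_symmetric_omega_rejected(self):
        obs = self._obs(2, 100)
        with pytest.raises(ValueError):
            wishart_loglik(obs, np.array([[0.25, 0.1], [0.0, 0.25]]))

    def test_degenerate_df_warns_then_rejects(self):
        obs = self._obs(3, 100)
        with pytest.warns(RuntimeWarning), pytest.raises(ValueError):
            WishartLikelihood(obs, df=2)

    def test_simulated_draws_prefer_true_scale_on_average(self, rng):
        true = np.array([[0.05, 0.02], [0.02, 0.06]])
        wrong = np.array([[0.08, -0.01], [-0.01, 0.04]])
        L = 300
        ll_true = ll_wrong = 0.0
        for _ in range(30):
            a = stats.wishart.rvs(L, true, random_state=rng)
            om = a / L
            np.fill_diagonal(om, 0.25)
            obs = AllelicCovariance(om, L)
            # evaluate both scales with matched diagonals via eta-free compare
            ll_true += wishart_loglik(obs, np.array([[0.25, 0.02],
                                                     [0.02, 0.25]]))
            ll_wrong += wishart_loglik(obs, np.array([[0.25, -0.01],
                                                      [-0.01, 0.25]]))
        assert ll_true > ll_wrong


class TestLogPrior:
    def _mp(self, alpha2=1.0, alpha0=0.5, w=None, gamma=0.1, eta=0.05):
        w = np.array([[0.5, 0.5], [0.2, 0.8]]) if w is None else w
        layers = [LayerParams(alpha0, 1.0, alpha2, 0.1),
                  LayerParams(0.3, 2.0, 1.2, 0.2)]
        return ModelParams(layers, w, gamma, np.full(2, eta))

    def test_alpha2_outside_support_rejected(self):
        mp = self._mp()
        mp.layers[0].alpha2 = 2.5  # bypass constructor check deliberately
        assert log_prior(mp) == -np.inf

    def test_negative_alpha0_rejected(self):
        mp = self._mp()
        mp.layers[0].alpha0 = -0.1
        assert log_prior(mp) == -np.inf

    def test_sparse_dirichlet_favors_corners(self):
        hyper = PriorSettings(dirichlet_concentration=0.5)
        even = self._mp(w=np.array([[0.5, 0.5], [0.5, 0.5]]))
        cornered = self._mp(w=np.array([[0.99, 0.01], [0.99, 0.01]]))
        assert log_prior(cornered, hyper) > log_prior(even, hyper)

    def test_matches_scipy_densities(self):
        mp = self._mp()
        hyper = PriorSettings(scale_alpha0=1.5, scale_alphaD=2.0,
                              scale_phi=0.5, scale_gamma=1.0, scale_eta=0.7,
                              dirichlet_concentration=0.8)
        expected = 0.0
        for lp in mp.layers:
            expected += stats.halfnorm.logpdf(lp.alpha0, scale=1.5)
            expected += stats.halfnorm.logpdf(lp.alphaD, scale=2.0)
            expected += stats.halfnorm.logpdf(lp.phi, scale=0.5)
            expected += stats.uniform.logpdf(lp.alpha2, 0, 2)
        expected += stats.halfnorm.logpdf(mp.gamma, scale=1.0)
        expected += stats.halfnorm.logpdf(mp.eta, scale=0.7).sum()
        for row in mp.w:
            expected += stats.dirichlet.logpdf(row, [0.8, 0.8])
        assert log_prior(mp, hyper) == pytest.approx(expected, abs=1e-9)

    def test_bad_scale_is_config_error(self):
        with pytest.raises(ValueError):
            PriorSettings(scale_phi=0.0)

    def test_nonspatial_likelihood_ignores_distances(self, grid_distances):
        # with alpha0 = 0 everywhere the parametric covariance, hence the
        # likelihood, is the same for any distance matrix
        n = grid_distances.n_samples
        mp = ModelParams([LayerParams(0.0, 1.0, 1.0, 0.05)], np.ones((n, 1)),
                         0.02, np.full(n, 0.18), spatial=False)
        om1 = admixed_covariance(mp, grid_distances).omega
        om2 = admixed_covariance(mp, np.zeros((n, n))).omega
        np.testing.assert_array_equal(om1, om2)
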