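"""Model fitting: proxy-process, two-rate learner, washout decay."""

import numpy as np
import pytest
import scipy.optimize

import proxylearn as pl
from proxylearn.structures import get_spec


def make_curve(sid, coeffs, e0=5.0, n=250, n_obs=74, sigma=0.0, seed=1):
    rng = np.random.default_rng(seed)
    spec = get_spec(sid)
    params = pl.ProxyModelParams.from_dict(sid, sigma=sigma, **coeffs)
    mask = pl.make_schedule(n, n_obs, rng)
    e, _ = pl.simulate_proxy(spec, params, e0, n - 1,
                             rng=rng if sigma > 0 else None)
    idx = np.flatnonzero(mask)
    return e[idx], idx, e0, n


class TestProxyFit:
    def test_noiseless_linear_recovery(self, fast_fit):
        obs, idx, e0, n = make_curve("1.1L", dict(b=-0.5), e0=8.0)
        res = pl.fit_proxy(obs, idx, e0, "1.1L", n_trials=n, config=fast_fit)
        assert res.params.as_dict()["b"] == pytest.approx(-0.5, abs=1e-4)
        assert res.sse < 1e-12

    def test_noiseless_second_order_recovery(self, fast_fit):
        obs, idx, e0, n = make_curve("2.1", dict(a=-0.2, b1=0.1, b2=-0.4))
        res = pl.fit_proxy(obs, idx, e0, "2.1", n_trials=n, config=fast_fit)
        d = res.params.as_dict()
        assert d["a"] == pytest.approx(-0.2, abs=1e-3)
        assert d["b1"] == pytest.approx(0.1, abs=1e-3)
        assert d["b2"] == pytest.approx(-0.4, abs=1e-3)

    def test_constant_observations_flagged_and_zero_sse(self, fast_fit):
        idx = np.arange(2, 30, 3)
        obs = np.full(idx.size, 4.0)
        model = pl.ProxyProcessModel(obs, idx, 4.0, "2.1", n_trials=30)
        assert model.constant_observations
        res = model.fit(fast_fit)
        assert res.sse == pytest.approx(0.0, abs=1e-10)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            pl.ProxyProcessModel([1.0, 2.0], [1, 2], 1.0, "2.1", n_trials=10)

    def test_fit_invariant_to_observation_order(self, fast_fit):
        obs, idx, e0, n = make_curve("1.1", dict(a=0.1, b=-0.3), sigma=0.05)
        perm = np.random.default_rng(0).permutation(obs.size)
        r1 = pl.fit_proxy(obs, idx, e0, "1.1", n_trials=n, config=fast_fit)
        r2 = pl.fit_proxy(obs[perm], idx[perm], e0, "1.1", n_trials=n, config=fast_fit)
        assert np.allclose(r1.theta, r2.theta)

    def test_more_starts_never_worse(self):
        obs, idx, e0, n = make_curve("2.1", dict(a=-0.1, b1=0.2, b2=-0.5), sigma=0.1)
        model = pl.ProxyProcessModel(obs, idx, e0, "2.1", n_trials=n)
        costs = [model.fit(pl.FitConfig(n_starts=k, seed=0)).best_objective
                 for k in (1, 4, 12)]
        assert costs[0] >= costs[1] >= costs[2]

    @pytest.mark.parametrize("objective", ["simulation", "anchored"])
    @pytest.mark.parametrize("sid", ["1.1L", "1.2", "2.1", "4.1"])
    def test_analytic_jacobian_matches_finite_differences(self, sid, objective):
        obs, idx, e0, n = make_curve("2.1", dict(a=0.0, b1=0.2, b2=-0.5),
                                     n=60, n_obs=18, sigma=0.1)
        model = pl.ProxyProcessModel(obs, idx, e0, sid, n_trials=n,
                                     objective=objective)
        theta = np.linspace(-0.2, 0.1, model.spec.n_free_params)
        J = model._jacobian(theta)
        Jfd = scipy.optimize.approx_fprime(theta, model._residuals, 1e-7)
        rel = np.abs(J - Jfd.reshape(J.shape)) / (1.0 + np.abs(J))
        assert rel.max() < 1e-4

    def test_summary_mentions_structure_and_stats(self, fast_fit):
        obs, idx, e0, n = make_curve("1.1L", dict(b=-0.5))
        res = pl.fit_proxy(obs, idx, e0, "1.1L", n_trials=n, config=fast_fit)
        text = res.summary()
        assert "1.1L" in text and "RMSE" in text


class TestSigmaEstimate:
    def test_zero_residuals(self):
        assert pl.estimate_sigma(np.zeros(10), 250) == 0.0

    def test_alternating_unit_residuals(self):
        sigma = pl.estimate_sigma([1, -1, 1, -1], 250)
        assert sigma == pytest.approx(1.0 / 250)

    def test_homogeneity(self, rng):
        r = rng.standard_normal(50)
        assert pl.estimate_sigma(2 * r, 100) == pytest.approx(
            2 * pl.estimate_sigma(r, 100))

    def test_sqrt_divisor_option(self, rng):
        r = rng.standard_normal(50)
        assert pl.estimate_sigma(r, 100, divisor="sqrt_n") == pytest.approx(
            pl.estimate_sigma(r, 100) * 10)


class TestMultiRateFit:
    @staticmethod
    def _curve(params, e0=4.0, n=250, seed=1, obs_noise=0.0):
        rng = np.random.default_rng(seed)
        mask = pl.make_schedule(n, 74, rng)
        avail = mask.copy()
        avail[0] = True
        e = pl.simulate_dpxmrml_curve(params, e0, n, available=avail,
                                      rng=rng if obs_noise > 0 else None,
                                      obs_noise=obs_noise)
        idx = np.flatnonzero(avail)
        return e[idx], idx, e0, n

    def test_noiseless_rate_recovery_within_five_percent(self):
        proxy = pl.ProxyModelParams.from_dict("2.1", a=-0.05, b1=0.1, b2=-0.3)
        truth = pl.DPxMRMLParams(Af=-0.5, As=0.95, Bf=0.4, Bs=-0.05, proxy=proxy)
        obs, idx, e0, n = self._curve(truth)
        res = pl.fit_dpxmrml(obs, idx, e0, proxy, n_trials=n,
                             config=pl.FitConfig(n_starts=30, seed=0))
        for name, target in truth.as_dict().items():
            assert getattr(res.params, name) == pytest.approx(target, rel=0.05), name

    def test_constraints_hold_on_noisy_fits(self):
        proxy = pl.ProxyModelParams.from_dict("2.1", a=0.0, b1=0.1, b2=-0.3)
        truth = pl.DPxMRMLParams(Af=-0.4, As=0.93, Bf=0.35, Bs=-0.03, proxy=proxy)
        for seed in range(3):
            obs, idx, e0, n = self._curve(truth, seed=seed, obs_noise=0.1)
            res = pl.fit_dpxmrml(obs, idx, e0, proxy, n_trials=n,
                                 config=pl.FitConfig(n_starts=10, seed=seed))
            assert res.params.As > res.params.Af
            assert res.params.Bf > res.params.Bs

    def test_zero_data_gives_zero_learning_rates(self):
        proxy = pl.ProxyModelParams.from_dict("2.1", a=0.0, b1=0.0, b2=0.0)
        idx = np.arange(0, 100, 3)
        res = pl.fit_dpxmrml(np.zeros(idx.size), idx, 0.0, proxy, n_trials=100,
                             config=pl.FitConfig(n_starts=5, seed=0))
        assert abs(res.params.Bf) < 0.05
        assert abs(res.params.Bs) < 0.05

    def test_fully_observed_fit_independent_of_proxy_coefficients(self):
        rng = np.random.default_rng(5)
        idx = np.arange(100)
        obs = 3 * 0.95 ** idx + 0.01 * rng.standard_normal(100)
        p1 = pl.ProxyModelParams.from_dict("2.1", a=0.0, b1=0.0, b2=0.0)
        p2 = pl.ProxyModelParams.from_dict("2.1", a=0.5, b1=0.4, b2=-0.6)
        cfg = pl.FitConfig(n_starts=6, seed=0)
        r1 = pl.fit_dpxmrml(obs, idx, obs[0], p1, n_trials=100, config=cfg)
        r2 = pl.fit_dpxmrml(obs, idx, obs[0], p2, n_trials=100, config=cfg)
        assert np.allclose(
            [r1.params.Af, r1.params.As, r1.params.Bf, r1.params.Bs],
            [r2.params.Af, r2.params.As, r2.params.Bf, r2.params.Bs],
        )


class TestWashoutFit:
    def test_noiseless_time_constant_exact(self):
        y = 6.0 * np.exp(-np.arange(30) / 5.0)
        fit = pl.fit_washout_exponential(y, pl.FitConfig(n_starts=20, seed=0))
        assert fit.tau == pytest.approx(5.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(6.0, abs=1e-6)

    def test_all_zero_series_flagged(self):
        fit = pl.fit_washout_exponential(np.zeros(10))
        assert fit.amplitude == 0.0
        assert fit.flagged

    def test_scaling_doubles_amplitude_not_tau(self):
        y = 4.0 * np.exp(-np.arange(25) / 8.0)
        cfg = pl.FitConfig(n_starts=20, seed=0)
        f1 = pl.fit_washout_exponential(y, cfg)
        f2 = pl.fit_washout_exponential(2 * y, cfg)
        assert f2.amplitude == pytest.approx(2 * f1.amplitude, rel=1e-6)
        assert f2.tau == pytest.approx(f1.tau, rel=1e-6)

    def test_non_decaying_data_flagged_at_bound(self):
        fit = pl.fit_washout_exponential(np.linspace(1, 2, 20),
                                         pl.FitConfig(n_starts=10, seed=0))
        assert fit.flagged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pl.fit_washout_exponential([1.0, 0.5])


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        g = pl.goodness_of_fit([1, 2, 3, 4], [1, 2, 3, 4], 2)
        assert g.rsquared == pytest.approx(1.0)
        assert g.rmse == 0.0

    def test_mean_predictor_gives_zero_rsquared(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        g = pl.goodness_of_fit(obs, np.full(4, obs.mean()), 1)
        assert g.rsquared == pytest.approx(0.0)

    def test_hand_computed_four_point_case(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.9])
        ss_res = np.sum((obs - pred) ** 2)
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        r2 = 1 - ss_res / ss_tot
        g = pl.goodness_of_fit(obs, pred, 1)
        assert g.rsquared == pytest.approx(r2)
        assert g.rsquared_adj == pytest.approx(1 - (1 - r2) * 3 / 2)
        assert g.rmse == pytest.approx(np.sqrt(ss_res / 4))

    def test_zero_variance_observations_flagged_nan(self):
        g = pl.goodness_of_fit([2.0, 2.0, 2.0], [2.0, 2.1, 1.9], 1)
        assert np.isnan(g.rsquared)
        assert g.rmse > 0

    def test_adjusted_never_exceeds_plain_rsquared(self, rng):
        obs = rng.standard_normal(30)
        pred = obs + 0.3 * rng.standard_normal(30)
        g = pl.goodness_of_fit(obs, pred, 3)
        assert g.rsquared_adj <= g.rsquared
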