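"""Proxy-process structures: registry, drift evaluation, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import proxylearn as pl
from proxylearn.structures import get_spec, registry


class TestRegistry:
    def test_eleven_structures_in_stable_order(self):
        specs = registry()
        assert [s.structure_id for s in specs] == [
            "1.1L", "1.1", "1.2", "1.3", "2.1", "3.1", "4.1", "5.1", "6.1", "7.1", "8.1"
        ]
        assert registry() == specs  # stable across calls

    @pytest.mark.parametrize("sid,order,nfree", [
        ("1.1L", 1, 1), ("1.1", 1, 2), ("1.2", 1, 3), ("1.3", 1, 4),
        ("2.1", 2, 3), ("5.1", 5, 6), ("8.1", 8, 9),
    ])
    def test_order_and_free_parameter_counts(self, sid, order, nfree):
        spec = get_spec(sid)
        assert spec.order == order
        assert spec.n_free_params == nfree

    def test_kth_order_coefficient_names(self):
        assert get_spec("2.1").param_names == ("a", "b1", "b2")

    def test_unknown_structure_rejected(self):
        with pytest.raises(KeyError):
            get_spec("9.1")


class TestDrift:
    @pytest.mark.parametrize("sid,coeffs,history,expected", [
        ("1.1L", dict(b=-0.5), [2.0], -1.0),
        ("1.1", dict(a=0.3, b=-0.5), [2.0], -0.7),
        ("1.2", dict(a=0.1, b=-0.3, c=0.05), [2.0], -0.3),
        ("1.3", dict(a=0.0, b=-0.2, c=0.1, d=-0.05), [2.0], -0.4),
        ("2.1", dict(a=0.0, b1=0.0, b2=0.0), [5.0, -3.0], 0.0),
        ("2.1", dict(a=0.1, b1=-0.2, b2=0.3), [1.0, 2.0], 0.1 - 0.4 + 0.3),
    ])
    def test_direct_substitution(self, sid, coeffs, history, expected):
        spec = get_spec(sid)
        params = pl.ProxyModelParams.from_dict(sid, **coeffs)
        assert pl.drift(spec, params, history) == pytest.approx(expected, abs=1e-12)

    def test_history_shorter_than_order_rejected(self):
        params = pl.ProxyModelParams.from_dict("3.1", a=0, b1=0, b2=0, b3=0)
        with pytest.raises(ValueError, match="history"):
            pl.drift(get_spec("3.1"), params, [1.0, 2.0])

    def test_most_recent_error_multiplies_b1(self):
        # history is most-recent-last: b1 acts on the last entry
        params = pl.ProxyModelParams.from_dict("2.1", a=0.0, b1=1.0, b2=0.0)
        assert pl.drift(get_spec("2.1"), params, [7.0, 3.0]) == pytest.approx(3.0)


class TestProxyStep:
    def test_hand_arithmetic(self):
        params = pl.ProxyModelParams.from_dict("1.1L", b=-0.5)
        assert pl.proxy_step(get_spec("1.1L"), params, [2.0]) == pytest.approx(1.0)

    def test_identity_update_with_zero_coefficients(self):
        params = pl.ProxyModelParams.from_dict("2.1", a=0, b1=0, b2=0)
        assert pl.proxy_step(get_spec("2.1"), params, [3.0, 1.5]) == pytest.approx(1.5)

    def test_noise_scale_matches_monte_carlo_mean(self, rng):
        params = pl.ProxyModelParams.from_dict("1.1L", b=-0.5, sigma=0.1)
        draws = rng.standard_normal(100_000)
        vals = [pl.proxy_step(get_spec("1.1L"), params, [2.0], d) for d in draws[:2000]]
        se = 0.1 / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * se


class TestSimulateProxy:
    def test_halving_sequence(self):
        params = pl.ProxyModelParams.from_dict("1.1L", b=-0.5)
        e, diverged = pl.simulate_proxy(get_spec("1.1L"), params, 8.0, 3)
        assert np.allclose(e, [8, 4, 2, 1])
        assert not diverged

    def test_affine_matches_closed_form(self):
        a, b, e0 = 0.3, -0.2, 5.0
        params = pl.ProxyModelParams.from_dict("1.1", a=a, b=b)
        e, _ = pl.simulate_proxy(get_spec("1.1"), params, e0, 100)
        n = np.arange(101)
        closed = (e0 + a / b) * (1 + b) ** n - a / b
        assert np.allclose(e, closed, rtol=1e-12, atol=1e-12)

    def test_zero_coefficients_hold_constant(self):
        params = pl.ProxyModelParams.from_dict("2.1", a=0, b1=0, b2=0)
        e, _ = pl.simulate_proxy(get_spec("2.1"), params, 4.2, 10)
        assert np.allclose(e, 4.2)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(b=st.floats(-1.9, 0.0), e0=st.floats(-8, 8))
    def test_linear_geometric_decay_property(self, b, e0):
        # non-explosive regime: |1 + b| <= 1, so the path stays below the cap
        params = pl.ProxyModelParams.from_dict("1.1L", b=b)
        e, _ = pl.simulate_proxy(get_spec("1.1L"), params, e0, 250)
        n = np.arange(251)
        assert np.allclose(e, e0 * (1 + b) ** n, rtol=1e-12, atol=1e-9)

    def test_explosive_growth_hits_cap_and_flags(self):
        params = pl.ProxyModelParams.from_dict("1.1L", b=0.4)
        e, diverged = pl.simulate_proxy(get_spec("1.1L"), params, 8.0, 250)
        assert diverged
        assert np.abs(e).max() <= 1e8

    def test_seeded_runs_bit_identical(self):
        params = pl.ProxyModelParams.from_dict("2.1", a=0.1, b1=-0.2, b2=-0.3, sigma=0.5)
        e1, _ = pl.simulate_proxy(get_spec("2.1"), params, 3.0, 50,
                                  rng=np.random.default_rng(7))
        e2, _ = pl.simulate_proxy(get_spec("2.1"), params, 3.0, 50,
                                  rng=np.random.default_rng(7))
        assert np.array_equal(e1, e2)

    def test_nonfinite_e0_rejected(self):
        params = pl.ProxyModelParams.from_dict("1.1L", b=-0.5)
        with pytest.raises(ValueError):
            pl.simulate_proxy(get_spec("1.1L"), params, np.nan, 5)


class TestSteadyState:
    def test_affine_fixed_point(self):
        params = pl.ProxyModelParams.from_dict("1.1", a=0.5, b=-0.25)
        ss = pl.steady_state_error(get_spec("1.1"), params, 8.0)
        assert ss.value == pytest.approx(-0.5 / -0.25, abs=1e-9)
        assert not ss.diverged

    def test_second_order_fixed_point(self):
        params = pl.ProxyModelParams.from_dict("2.1", a=-0.3, b1=0.1, b2=-0.25)
        ss = pl.steady_state_error(get_spec("2.1"), params, 1.0)
        assert ss.value == pytest.approx(-(-0.3) / (0.1 - 0.25), abs=1e-6)

    def test_zero_coefficients_stay_at_e0(self):
        params = pl.ProxyModelParams.from_dict("2.1", a=0, b1=0, b2=0)
        ss = pl.steady_state_error(get_spec("2.1"), params, 3.3)
        assert ss.value == pytest.approx(3.3)

    def test_divergent_dynamics_flagged(self):
        params = pl.ProxyModelParams.from_dict("1.1L", b=0.5)
        ss = pl.steady_state_error(get_spec("1.1L"), params, 1.0)
        assert ss.diverged

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(a=st.floats(-0.3, 0.3), b1=st.floats(-0.4, 0.4), b2=st.floats(-0.45, -0.05))
    def test_stable_second_order_converges_to_fixed_point(self, a, b1, b2):
        # restrict to roots of z^2 - (1+b1)z - b2 inside the unit circle
        roots = np.roots([1.0, -(1 + b1), -b2])
        if np.max(np.abs(roots)) > 0.95 or abs(b1 + b2) < 1e-3:
            return
        params = pl.ProxyModelParams.from_dict("2.1", a=a, b1=b1, b2=b2)
        ss = pl.steady_state_error(get_spec("2.1"), params, 1.0)
        if not ss.diverged:
            assert ss.value == pytest.approx(-a / (b1 + b2), abs=1e-6)


class TestParamValidation:
    def test_wrong_coefficient_set_rejected(self):
        with pytest.raises(ValueError):
            pl.ProxyModelParams.from_dict("1.1L", a=1.0, b=0.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            pl.ProxyModelParams.from_dict("1.1L", b=0.0, sigma=-0.1)
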