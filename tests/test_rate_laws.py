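"""Rate surfaces, limiting-regime reductions and parameter extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import enfetsim as es
from enfetsim.rate_laws import (
    FitError,
    InitialRateOrderEstimator,
    ProgressCurve,
    RateDataset,
    RateLawParams,
)
from enfetsim.synthetic import FixtureSpec, generate_progress_curves, generate_rate_dataset


class TestRateSurfaces:
    def test_half_saturation(self, gox_params):
        assert es.mm_rate(gox_params, 0.01) == pytest.approx(0.009, rel=1e-12)

    def test_zero_substrate_zero_rate(self, gox_params):
        assert es.mm_rate(gox_params, 0.0) == 0.0

    def test_gox_rate_at_5mM(self, gox_params):
        # 0.018 * 5 / (10 + 5) mol/(L s)
        assert es.mm_rate(gox_params, 5e-3) == pytest.approx(0.006, rel=1e-12)

    def test_hill_half_saturation_any_h(self):
        for h in (0.3, 1.0, 2.0, 4.0):
            p = RateLawParams(1.74e-3, 1e-3, h, "hill")
            assert es.hill_rate(p, 1e-3) == pytest.approx(1.74e-3 / 2, rel=1e-12)

    def test_hill_cooperative_value(self):
        # v_max = 1.74 mM/s, K_M = 1 mM, h = 4, A = 2 mM -> v_max*16/17
        p = RateLawParams(1.74e-3, 1e-3, 4.0, "hill")
        assert es.hill_rate(p, 2e-3) == pytest.approx(1.74e-3 * 16 / 17, rel=1e-12)
        assert es.hill_rate(p, 2e-3) == pytest.approx(1.6376e-3, rel=1e-4)

    @settings(derandomize=True, max_examples=40)
    @given(A=st.floats(1e-9, 1.0))
    def test_hill_h1_equals_mm(self, A):
        mm = RateLawParams(0.018, 0.01)
        hill = RateLawParams(0.018, 0.01, 1.0, "hill")
        assert es.hill_rate(hill, A) == es.mm_rate(mm, A)

    def test_negative_concentration_rejected(self, gox_params):
        with pytest.raises(ValueError):
            es.mm_rate(gox_params, -1e-3)
        with pytest.raises(ValueError):
            es.hill_rate(RateLawParams(1.0, 1.0, 2.0, "hill"), -1.0)

    def test_mm_concave_increasing(self, gox_params):
        A = np.linspace(1e-5, 0.1, 400)
        v = es.mm_rate(gox_params, A)
        assert np.all(np.diff(v) > 0)
        assert np.all(np.diff(v, 2) < 0)

    def test_hill_sigmoidal_single_inflection(self):
        p = RateLawParams(1.0, 1e-3, 3.0, "hill")
        A = np.linspace(1e-6, 1e-2, 2000)
        d2 = np.diff(es.hill_rate(p, A), 2)
        sign_changes = int(np.sum(np.diff(np.sign(d2[np.abs(d2) > 1e-18])) != 0))
        assert sign_changes == 1


class TestLimitingRateConstant:
    def test_zero_order_is_vmax(self, gox_params):
        assert es.limiting_rate_constant(gox_params, "zero_order") == (0.018, 0.0)

    def test_first_order_is_vmax_over_km(self, gox_params):
        k, n = es.limiting_rate_constant(gox_params, "first_order")
        assert (k, n) == (pytest.approx(1.8, rel=1e-12), 1.0)

    def test_tyrosinase_first_order(self):
        # v_max = 0.055 mM/s, K_M = 1.13 mM -> 0.0487 s^-1
        p = RateLawParams(0.055e-3, 1.13e-3)
        k, n = es.limiting_rate_constant(p, "first_order")
        assert k == pytest.approx(0.055 / 1.13, rel=1e-12)
        assert k == pytest.approx(0.0487, rel=1e-3)

    def test_h_order_requires_hill(self, gox_params):
        with pytest.raises(ValueError):
            es.limiting_rate_constant(gox_params, "h_order")
        p = RateLawParams(1.74e-3, 1e-3, 2.0, "hill")
        k, n = es.limiting_rate_constant(p, "h_order")
        assert (k, n) == (pytest.approx(1.74e-3 / 1e-6, rel=1e-12), 2.0)

    def test_limits_match_rate_surface(self, gox_params):
        # A = K_M * 1e-4: v/A within 0.02% of the first-order constant
        a_low = gox_params.K_M * 1e-4
        k1, _ = es.limiting_rate_constant(gox_params, "first_order")
        assert es.mm_rate(gox_params, a_low) / a_low == pytest.approx(k1, rel=2e-4)
        # A = K_M * 1e4: v within 0.02% of v_max
        a_high = gox_params.K_M * 1e4
        k0, _ = es.limiting_rate_constant(gox_params, "zero_order")
        assert es.mm_rate(gox_params, a_high) == pytest.approx(k0, rel=2e-4)


class TestTurnover:
    def test_gox_turnover(self):
        assert es.k2_from_loading(0.018, es.EnzymeLoading(2e-5)) == pytest.approx(900.0)

    def test_identity_and_acetylcholinesterase_value(self):
        assert es.k2_from_loading(2e-5, es.EnzymeLoading(2e-5)) == 1.0
        assert es.k2_from_loading(1.74e-3, es.EnzymeLoading(2e-5)) == pytest.approx(87.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            es.k2_from_loading(-1.0, es.EnzymeLoading(1e-5))
        with pytest.raises(ValueError):
            es.EnzymeLoading(0.0)


class TestLineweaverBurk:
    def test_noiseless_roundtrip(self, gox_params):
        grid = np.array([1e-3, 2e-3, 5e-3, 1e-2, 2e-2])
        data = generate_rate_dataset(FixtureSpec(truth=gox_params, grid=grid))
        fit = es.fit_lineweaver_burk(data)
        assert fit.v_max == pytest.approx(0.018, rel=1e-9)
        assert fit.K_M == pytest.approx(0.01, rel=1e-9)

    def test_noiseless_roundtrip_second_constant_set(self):
        truth = RateLawParams(1.74e-3, 0.01)
        data = generate_rate_dataset(
            FixtureSpec(truth=truth, grid=np.geomspace(1e-3, 1e-1, 8))
        )
        fit = es.fit_lineweaver_burk(data)
        assert fit.v_max == pytest.approx(truth.v_max, rel=1e-9)
        assert fit.K_M == pytest.approx(truth.K_M, rel=1e-9)

    def test_noisy_recovery_within_5_percent(self, gox_params):
        data = generate_rate_dataset(
            FixtureSpec(
                truth=gox_params,
                grid=np.geomspace(1e-3, 1e-1, 20),
                noise_model="multiplicative_gaussian",
                sigma=0.01,
                seed=0,
            )
        )
        fit = es.fit_lineweaver_burk(data)
        assert fit.v_max == pytest.approx(0.018, rel=0.05)
        assert fit.K_M == pytest.approx(0.01, rel=0.05)

    def test_diagnostics_exposed(self, gox_params):
        data = generate_rate_dataset(
            FixtureSpec(truth=gox_params, grid=np.geomspace(1e-3, 1e-1, 10))
        )
        est = es.LineweaverBurkRegressor().fit(data.A, data.v)
        assert est.r_squared_ == pytest.approx(1.0, abs=1e-12)
        assert est.residuals_.shape == (10,)
        np.testing.assert_allclose(est.predict(data.A), data.v, rtol=1e-9)

    def test_inconsistent_data_raises(self):
        # rates increasing super-linearly in 1/A force a negative intercept
        A = np.array([1e-3, 2e-3, 4e-3, 8e-3])
        v = np.array([1.0, 10.0, 100.0, 1000.0])
        with pytest.raises(FitError):
            es.fit_lineweaver_burk(RateDataset(A=A, v=v))

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            es.fit_lineweaver_burk(RateDataset(A=np.array([1e-3, 2e-3]), v=np.array([1.0, 2.0])))

    def test_nonlinear_mm_cross_check(self, gox_params):
        data = generate_rate_dataset(
            FixtureSpec(truth=gox_params, grid=np.geomspace(1e-3, 1e-1, 12))
        )
        lb = es.fit_lineweaver_burk(data)
        nl = es.fit_mm_nonlinear(data)
        assert nl.v_max == pytest.approx(lb.v_max, rel=1e-6)
        assert nl.K_M == pytest.approx(lb.K_M, rel=1e-6)


class TestHillFit:
    @pytest.mark.parametrize("h_true", [0.3, 2.0])
    def test_noiseless_roundtrip(self, h_true):
        truth = RateLawParams(1.74e-3, 1e-3, h_true, "hill")
        data = generate_rate_dataset(
            FixtureSpec(truth=truth, grid=np.geomspace(1e-5, 1e-1, 15))
        )
        fit = es.fit_hill(data)
        assert fit.v_max == pytest.approx(truth.v_max, rel=1e-6)
        assert fit.K_M == pytest.approx(truth.K_M, rel=1e-6)
        assert fit.h == pytest.approx(h_true, rel=1e-6)

    def test_nests_michaelis_menten(self, gox_params):
        data = generate_rate_dataset(
            FixtureSpec(truth=gox_params, grid=np.geomspace(1e-4, 1e-1, 10))
        )
        hill = es.fit_hill(data)
        lb = es.fit_lineweaver_burk(data)
        assert hill.h == pytest.approx(1.0, abs=1e-6)
        assert hill.v_max == pytest.approx(lb.v_max, rel=1e-6)
        assert hill.K_M == pytest.approx(lb.K_M, rel=1e-6)

    def test_determinism(self, gox_params):
        data = generate_rate_dataset(
            FixtureSpec(
                truth=gox_params,
                grid=np.geomspace(1e-4, 1e-1, 12),
                noise_model="multiplicative_gaussian",
                sigma=0.02,
                seed=7,
            )
        )
        a = es.HillRegressor().fit(data.A, data.v)
        b = es.HillRegressor().fit(data.A, data.v)
        assert (a.v_max_, a.K_M_, a.h_) == (b.v_max_, b.K_M_, b.h_)


class TestInitialRateOrderEstimation:
    @pytest.mark.parametrize(
        "n_true, k_true", [(1.0, 0.1439), (2.0, 440.0)]
    )
    def test_noiseless_order_recovery(self, n_true, k_true):
        fs = FixtureSpec(
            truth=es.KineticsSpec(A0=1e-3, n=n_true, k=k_true),
            A0_values=(1e-3, 2e-3, 5e-3),
        )
        n_est, k_est = es.estimate_order_initial_rates(generate_progress_curves(fs))
        assert n_est == pytest.approx(n_true, abs=0.01)
        assert k_est == pytest.approx(k_true, rel=0.01)

    def test_standard_errors_reported(self):
        fs = FixtureSpec(
            truth=es.KineticsSpec(A0=1e-3, n=2.0, k=440.0),
            A0_values=(1e-3, 2e-3, 4e-3, 8e-3),
        )
        est = InitialRateOrderEstimator().fit(generate_progress_curves(fs))
        assert est.n_stderr_ >= 0.0
        assert est.k_stderr_ >= 0.0

    def test_single_series_rejected(self):
        fs = FixtureSpec(truth=es.KineticsSpec(A0=1e-3, n=2.0, k=440.0), A0_values=(1e-3,))
        with pytest.raises(ValueError):
            es.estimate_order_initial_rates(generate_progress_curves(fs))

    def test_decreasing_product_gives_estimation_error(self):
        t = np.linspace(0.0, 1.0, 6)
        curves = [
            ProgressCurve(t=t, P=-1e-4 * t * a0 / 1e-3, A0=a0) for a0 in (1e-3, 2e-3)
        ]
        with pytest.raises(FitError):
            es.estimate_order_initial_rates(curves)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"v_max": 0.0, "K_M": 1e-3},
            {"v_max": 1e-3, "K_M": -1.0},
            {"v_max": 1e-3, "K_M": 1e-3, "h": 0.0},
            {"v_max": 1e-3, "K_M": 1e-3, "h": 2.0, "model_tag": "michaelis_menten"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RateLawParams(**kwargs)

    def test_rate_dataset_requires_positive_values(self):
        with pytest.raises(ValueError):
            RateDataset(A=np.array([1e-3, -1e-3, 2e-3]), v=np.array([1.0, 1.0, 1.0]))
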