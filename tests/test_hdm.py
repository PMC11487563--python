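"""Hemodynamic forward model: ODEs, integration, Volterra kernels."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from boldhrf import hdm


@pytest.fixture()
def params():
    return hdm.HDMParams()


def reference_bold(p, onsets, duration_s, eval_times, event_len=hdm.DEFAULT_DT):
    """Independent oracle: integrate the natural-space ODE system with an
    adaptive high-order solver at tight tolerance."""
    onsets = np.atleast_1d(onsets)

    def z(t):
        return float(np.any((t >= onsets) & (t < onsets + event_len)))

    def rhs(t, x):
        s, f, v, q = x
        fout = v ** (1.0 / p.alpha)
        ext = (1.0 - (1.0 - p.e0) ** (1.0 / f)) / p.e0
        return [
            p.beta * z(t) - p.kappa * s - p.gamma * (f - 1.0),
            s,
            p.transit_rate * (f - fout),
            p.transit_rate * (f * ext - fout * q / v),
        ]

    sol = solve_ivp(rhs, (0.0, duration_s), [0.0, 1.0, 1.0, 1.0],
                    t_eval=eval_times, rtol=1e-10, atol=1e-12, max_step=0.05)
    k1, k2, k3 = p.bold_coefficients()
    v, q = sol.y[2], sol.y[3]
    return 100.0 * p.v0 * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))


class TestDerivatives:
    def test_rest_is_fixed_point(self, params):
        d = hdm.dstate_dt(hdm.HDMState(), 0.0, params)
        assert np.allclose(d, 0.0)

    def test_input_drives_only_vasoactive_signal(self, params):
        ds, df, dv, dq = hdm.dstate_dt(hdm.HDMState(), 1.0, params)
        assert ds == pytest.approx(params.beta)
        assert (df, dv, dq) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("alpha", [0.2, 0.32, 0.5])
    def test_outflow_is_unity_at_rest_volume(self, alpha):
        assert 1.0 ** (1.0 / alpha) == 1.0

    def test_nonfinite_state_rejected(self, params):
        state = hdm.HDMState(s=np.nan)
        with pytest.raises(ValueError):
            hdm.dstate_dt(state, 0.0, params)


class TestObservation:
    def test_rest_gives_zero_signal(self, params):
        assert hdm.bold_from_state(hdm.HDMState(), params) == 0.0

    def test_k3_vanishes_at_unit_vascular_ratio(self):
        p = hdm.HDMParams(eps_h=1.0)
        assert p.bold_coefficients()[2] == 0.0

    def test_k1_arithmetic(self):
        # 4.3 * 40.3 * 0.4 * 0.03
        p = hdm.HDMParams(theta0=40.3, e0=0.4, te=0.03)
        assert p.bold_coefficients()[0] == pytest.approx(2.07948, abs=1e-10)


class TestIntegration:
    def test_no_input_no_output(self, params):
        y = hdm.integrate(params, hdm.NeuralInput(np.zeros(100), 0.375))
        assert np.allclose(y, 0.0, atol=1e-12)

    def test_single_event_peak_then_undershoot(self, params):
        """The impulse response peaks between 3 and 7 s, then undershoots;
        the whole curve agrees with an adaptive-solver reference."""
        dt = hdm.DEFAULT_DT
        ni = hdm.NeuralInput.from_events([0.0], dt, dt, 40.0)
        y = hdm.integrate(params, ni)
        t = np.arange(len(y)) * dt
        assert 3.0 <= t[np.argmax(y)] <= 7.0
        assert y.max() > 0
        assert y.min() < 0  # post-peak undershoot
        assert t[np.argmin(y)] > t[np.argmax(y)]
        ref = reference_bold(params, [0.0], t[-1], t)
        rel = np.linalg.norm(y - ref) / np.linalg.norm(ref)
        # the onset transient is only marginally resolved at the default
        # 0.375 s step; agreement with the adaptive reference is ~2e-3
        assert rel < 5e-3
        assert abs(t[np.argmax(ref)] - t[np.argmax(y)]) <= 0.375

    def test_step_halving_convergence(self, params):
        """Relative L2 change under dt halving is below 1e-3 and the error
        versus a 0.01 s reference scales like a fourth-order method."""
        ni1 = hdm.NeuralInput.from_events([0.0], 0.375, 0.375, 30.0)
        ni2 = hdm.NeuralInput.from_events([0.0], 0.375, 0.1875, 30.0)
        y1 = hdm.integrate(params, ni1)
        y2 = hdm.integrate(params, ni2)
        t1 = np.arange(len(y1)) * 0.375
        rel = (np.linalg.norm(y1 - y2[::2]) / np.linalg.norm(y1))
        assert rel < 1e-3
        # order check against the adaptive reference (event duration fixed
        # at 0.375 s so both grids resolve the same input)
        ref = reference_bold(params, [0.0], t1[-1], t1, event_len=0.375)
        e1 = np.linalg.norm(y1 - ref)
        e2 = np.linalg.norm(y2[::2] - ref)
        assert 8.0 < e1 / e2 < 40.0  # ~2^4 for RK4

    def test_return_to_rest(self, params):
        """After input ceases, all states relax back to the fixed point."""
        dt = hdm.DEFAULT_DT
        ni = hdm.NeuralInput.from_events([0.0], dt, dt, 80.0)
        y = hdm.integrate(params, ni)
        t = np.arange(len(y)) * dt
        assert np.all(np.abs(y[t >= 60.0]) < 1e-3)

    def test_divergence_reports_parameter_regime(self):
        # a negative feedback rate makes the flow-signal oscillator
        # genuinely unstable, so the trajectory must blow up
        p = hdm.HDMParams(gamma=-5.0, beta=5.0)
        ni = hdm.NeuralInput.from_events([0.0], 0.375, 0.375, 200.0)
        with pytest.raises(FloatingPointError, match="gamma"):
            hdm.integrate(p, ni)


class TestDownsampling:
    def test_constant_series(self):
        y = np.full(100, 3.5)
        out = hdm.downsample_to_scans(y, 0.375, 2.0, 10)
        assert np.allclose(out, 3.5)

    def test_linear_ramp(self):
        y = np.arange(100) * 1.0  # y(t) = t / dt with dt = 1
        out = hdm.downsample_to_scans(y, 1.0, 2.0, 5)
        assert np.allclose(out, [0, 2, 4, 6, 8])

    def test_matches_interpolation_oracle(self, rng):
        y = rng.standard_normal(200)
        out = hdm.downsample_to_scans(y, 0.375, 1.97, 30, offset_s=0.1)
        times = np.arange(30) * 1.97 + 0.1
        ref = np.interp(times, np.arange(200) * 0.375, y)
        assert np.max(np.abs(out - ref)) < 1e-12

    def test_out_of_range_scan_times_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            hdm.downsample_to_scans(np.zeros(10), 0.375, 2.0, 10)


class TestVolterraKernels:
    def test_k2_symmetric(self, params):
        lags = np.arange(0.0, 12.1, 0.75)
        K2 = hdm.volterra_kernel2(params, lags)
        assert np.array_equal(K2, K2.T)

    def test_linear_regime_second_order_vanishes(self, params):
        """At 1% of the default efficacy the pairwise interaction kernel is
        negligible relative to the first-order kernel."""
        lags = np.arange(0.0, 16.1, 0.75)
        small = hdm.with_params(params, beta=0.01 * params.beta)
        k1 = hdm.volterra_kernel1(small, lags)
        K2 = hdm.volterra_kernel2(small, lags)
        assert np.max(np.abs(K2)) / np.max(np.abs(k1)) < 0.05

    def test_close_pair_saturates(self, params):
        """Two stimuli 2 s apart produce less than the sum of two isolated
        peak responses (refractoriness at short SOA)."""
        dt = hdm.DEFAULT_DT
        ni_pair = hdm.NeuralInput.from_events([0.0, 2.25], dt, dt, 40.0)
        ni_one = hdm.NeuralInput.from_events([0.0], dt, dt, 40.0)
        y_pair = hdm.integrate(params, ni_pair)
        y_one = hdm.integrate(params, ni_one)
        assert y_pair.max() < 2 * y_one.max()

    def test_small_beta_linearises_to_first_kernel(self, params):
        """For weak input the full response equals the convolution of the
        event train with the first-order kernel (5% L2)."""
        dt = hdm.DEFAULT_DT
        small = hdm.with_params(params, beta=0.02)
        onsets = np.array([0.0, 6.0, 15.0])
        ni = hdm.NeuralInput.from_events(onsets, dt, dt, 60.0)
        y = hdm.integrate(small, ni)
        t = np.arange(len(y)) * dt
        lag_grid = np.arange(0.0, 40.0 + dt / 2, dt)
        k1 = hdm.volterra_kernel1(small, lag_grid)
        y_lin = np.zeros_like(y)
        for t0 in onsets:
            lags = t - t0
            m = (lags >= 0) & (lags <= 40.0)
            y_lin[m] += np.interp(lags[m], lag_grid, k1)
        assert np.linalg.norm(y - y_lin) / np.linalg.norm(y) < 0.05


class TestSecondOrderVarianceFraction:
    def test_isolated_event_has_no_second_order_variance(self, params):
        frac = hdm.second_order_variance_fraction(np.array([0.0]), params)
        assert frac == 0.0

    def test_linear_limit(self, params):
        onsets = np.arange(0.0, 40.0, 4.0)
        small = hdm.with_params(params, beta=0.01)
        assert hdm.second_order_variance_fraction(onsets, small) < 0.01

    def test_dense_design_more_nonlinear_than_sparse(self, params):
        dense = hdm.second_order_variance_fraction(np.arange(0.0, 60.0, 2.25),
                                                   params)
        sparse = hdm.second_order_variance_fraction(np.arange(0.0, 600.0, 20.25),
                                                    params)
        assert dense > sparse
        assert 0.0 <= sparse <= dense <= 1.0

    def test_empty_variance_rejected(self):
        p = hdm.HDMParams(beta=0.0)
        with pytest.raises(ValueError, match="zero variance"):
            hdm.second_order_variance_fraction(np.array([0.0]), p)
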