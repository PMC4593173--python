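"""Unit and property tests for the neural mass simulation layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve

from ssvepflow import (
    ColumnConstants,
    DivergenceError,
    DoubleColumnParams,
    InputSeries,
    SignalSegment,
    power_spectrum,
    sigmoid,
    simulate_double_column,
    simulate_single_column,
)

CONST = ColumnConstants()


class TestSigmoid:
    def test_midpoint_is_half_max(self):
        assert sigmoid(CONST.v0, CONST) == pytest.approx(CONST.e0)

    def test_saturation_limits(self):
        assert sigmoid(1e6, CONST) == pytest.approx(2 * CONST.e0)
        assert sigmoid(-1e6, CONST) == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_at_zero(self):
        # independent direct evaluation of 2 e0 / (1 + exp(r (v0 - v)))
        expected = 2 * 2.5 / (1 + math.exp(0.56 * (6.0 - 0.0)))
        assert sigmoid(0.0, CONST) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(
        v1=st.floats(-50, 50),
        v2=st.floats(-50, 50),
    )
    def test_strictly_increasing_and_bounded(self, v1, v2):
        s1, s2 = sigmoid(v1, CONST), sigmoid(v2, CONST)
        assert 0 < s1 < 2 * CONST.e0
        if v2 - v1 > 1e-9:  # resolvable separation in float64
            assert s1 < s2


def _constant_input(value, duration=8.0, fs=1000.0):
    return InputSeries(np.full(int(duration * fs), float(value)), fs)


class TestSimulation:
    def test_deterministic(self, fixture_8hz):
        again = simulate_double_column(
            fixture_8hz.true_params, fixture_8hz.p, fixture_8hz.p_prime, burn_in=1.0
        )
        assert np.array_equal(again.data, fixture_8hz.segment.data)

    def test_decoupling_matches_single_columns_exactly(self):
        """K1 = K2 = 0 must reproduce two isolated columns bit for bit."""
        rng = np.random.default_rng(5)
        p = InputSeries(rng.uniform(120, 320, 2000), 1000.0)
        pp = InputSeries(rng.uniform(120, 320, 2000), 1000.0)
        params = DoubleColumnParams(95.0, 70.0, 0.0, 0.0)
        double = simulate_double_column(params, p, pp)
        u1 = simulate_single_column(95.0, p)
        u2 = simulate_single_column(70.0, pp)
        assert np.array_equal(double.channel("u1"), u1.channel("u"))
        assert np.array_equal(double.channel("u2"), u2.channel("u"))

    def test_constant_input_converges_to_fixed_point_oracle(self):
        """With a noiseless constant drive the trajectory settles on the
        equilibrium of the state equations, found here by an independent
        algebraic root solve."""
        C1, C2, K1, K2 = 90.0, 85.0, 2000.0, 300.0
        p0, pp0 = 220.0, 220.0
        A, B, a, b, ad = CONST.A, CONST.B, CONST.a, CONST.b, CONST.a_d
        S = lambda v: sigmoid(v, CONST)

        def residual(u):
            # at equilibrium every state is an algebraic function of the two
            # pyramidal potentials; two consistency equations remain
            u1, u2 = u
            y01 = (A / a) * S(u1)
            y02 = (A / a) * S(u2)
            y21 = (B / b) * 0.25 * C1 * S(0.25 * C1 * y01)
            y22 = (B / b) * 0.25 * C2 * S(0.25 * C2 * y02)
            y61 = (A / ad) * S(u1)
            y62 = (A / ad) * S(u2)
            return [
                u1 + y21 - (A / a) * (p0 + 0.8 * C1 * S(C1 * y01) + K2 * y62),
                u2 + y22 - (A / a) * (pp0 + 0.8 * C2 * S(C2 * y02) + K1 * y61),
            ]

        seg = simulate_double_column(
            DoubleColumnParams(C1, C2, K1, K2), _constant_input(p0), _constant_input(pp0)
        )
        u_sim = np.array([seg.channel("u1")[-1], seg.channel("u2")[-1]])
        # the trajectory has settled (last 0.5 s essentially constant) ...
        assert np.ptp(seg.data[:, -500:], axis=1).max() < 1e-8
        # ... on the equilibrium nearest the endpoint (multistable system)
        u_star = fsolve(residual, u_sim + 1.0, xtol=1e-13)
        assert u_sim == pytest.approx(u_star, abs=1e-6)

    def test_bounded_within_parameter_box(self, fixture_8hz):
        assert np.isfinite(fixture_8hz.segment.data).all()
        assert np.abs(fixture_8hz.segment.data).max() < 1e3

    def test_divergence_raises_naming_parameters(self):
        # rate constants far above the RK4 stability limit at dt = 1 ms make
        # the integration blow up; the error must name the parameter set
        fast = ColumnConstants(a=5000.0, b=2500.0)
        params = DoubleColumnParams(90.0, 90.0, 2000.0, 300.0, fast, fast)
        p = _constant_input(320.0, duration=2.0)
        with pytest.raises(DivergenceError, match="K1=2000"):
            simulate_double_column(params, p, p)

    def test_input_length_mismatch_rejected(self):
        p = _constant_input(200.0, duration=1.0)
        pp = _constant_input(200.0, duration=2.0)
        with pytest.raises(ValueError, match="share sampling rate and length"):
            simulate_double_column(DoubleColumnParams(90, 90, 2000, 300), p, pp)

    def test_finer_integration_step_changes_little(self, fixture_8hz):
        """Halving dt (with decimation back to the sample grid) is an
        integration-accuracy check: the output must be essentially
        unchanged, confirming dt = 1 ms resolves the dynamics."""
        from ssvepflow.neural_mass import simulate_double_column_batch

        E = fixture_8hz.true_params.as_vector()[None, :]
        u_coarse, _ = simulate_double_column_batch(
            E, fixture_8hz.p, fixture_8hz.p_prime, dt=1e-3, burn_in=1.0
        )
        u_fine, _ = simulate_double_column_batch(
            E, fixture_8hz.p, fixture_8hz.p_prime, dt=0.5e-3, burn_in=1.0
        )
        assert u_fine.shape == u_coarse.shape
        rel = np.linalg.norm(u_fine - u_coarse) / np.linalg.norm(u_coarse)
        assert rel < 1e-6

    def test_single_column_canonical_regime_is_band_limited(self):
        """A lone column with the canonical connectivity constant and pure
        noise drive oscillates with its spectral mass below 30 Hz."""
        rng = np.random.default_rng(7)
        p = InputSeries(rng.uniform(120, 320, 6000), 1000.0)
        seg = simulate_single_column(135.0, p, burn_in=1.0)
        f, P = power_spectrum(seg, "u")
        assert P[(f > 0) & (f < 30)].sum() > 0.9 * P[f > 0].sum()
        # and it genuinely oscillates
        assert seg.channel("u").std() > 0.5


class TestStimulusEntrainment:
    def test_only_8hz_drive_evokes_strong_stimulus_frequency_response(self):
        """With inverted-regime parameters the occipital output shows a clear
        8 Hz response for the 8 Hz drive, while the 44/84 Hz drives leave no
        comparable response at their own stimulus frequencies (the PSP chain
        low-passes them): the control-referenced power increment at the
        stimulus frequency is more than an order of magnitude larger for
        8 Hz."""
        from ssvepflow import StimulusSpec, generate_inversion_fixture

        params = DoubleColumnParams(90.0, 90.0, 2400.0, 350.0)
        spectra = {}
        for condition in ("control", "8", "44", "84"):
            # stimulus-locked average over segments: the pulse train is
            # locked to segment onset, so averaging suppresses the
            # noise-driven background while keeping the evoked response
            mean_u1 = np.mean(
                [
                    generate_inversion_fixture(
                        params, StimulusSpec(condition=condition), seed=31 + k
                    ).segment.channel("u1")
                    for k in range(8)
                ],
                axis=0,
            )
            f, P = power_spectrum(SignalSegment(mean_u1[None, :], 1000.0, ("u1",)), "u1")
            spectra[condition] = (f, P)

        def increment(condition):
            f, P = spectra[condition]
            f0, P0 = spectra["control"]
            i = np.argmin(np.abs(f - float(condition)))
            return P[i] - P0[i]

        assert increment("8") > 10 * abs(increment("44"))
        assert increment("8") > 10 * abs(increment("84"))
        # and the 8 Hz bin is the local spectral maximum of its neighbourhood
        f, P = spectra["8"]
        window = (f >= 5) & (f <= 11)
        assert f[window][np.argmax(P[window])] == pytest.approx(8.0, abs=f[1] - f[0])


class TestPowerSpectrum:
    def test_pure_tone_peaks_at_tone_frequency(self):
        fs = 1000.0
        t = np.arange(3000) / fs
        seg = SignalSegment(np.sin(2 * np.pi * 8.0 * t)[None, :], fs, ("x",))
        f, P = power_spectrum(seg, "x")
        assert f[np.argmax(P)] == pytest.approx(8.0, abs=f[1] - f[0])

    def test_zero_signal_gives_zero_power(self):
        seg = SignalSegment(np.zeros((1, 2000)), 1000.0, ("x",))
        _, P = power_spectrum(seg, "x")
        assert np.all(P == 0)

    def test_parseval_white_noise(self, rng):
        x = rng.normal(0, 2.0, 20000)
        seg = SignalSegment(x[None, :], 1000.0, ("x",))
        f, P = power_spectrum(seg, "x")
        total = np.trapezoid(P, f)
        assert total == pytest.approx(x.var(), rel=0.05)

    def test_unknown_channel_is_lookup_error(self, fixture_8hz):
        with pytest.raises(KeyError, match="nope"):
            power_spectrum(fixture_8hz.segment, "nope")


class TestSegmentContainer:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="not unique"):
            SignalSegment(np.zeros((2, 10)), 1000.0, ("a", "a"))

    def test_label_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel labels"):
            SignalSegment(np.zeros((2, 10)), 1000.0, ("a",))
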