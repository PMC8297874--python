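"""Mobius-wave primitives, monocomponent and multicomponent fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmmst.waves import (
    FMMWave,
    TimeGrid,
    fit_mono,
    fit_multi,
    phase,
    r_squared,
    wave_value,
)

TWO_PI = 2 * np.pi


def circdist(a, b):
    return np.abs(np.angle(np.exp(1j * (a - b))))


class TestPhase:
    def test_sinusoid_limit(self):
        """At omega=1 the Mobius phase is the linear phase beta + (t - alpha)."""
        theta = np.linspace(0, TWO_PI, 57, endpoint=False)
        got = phase(theta, alpha=1.2, beta=0.7, omega=1.0)
        expect = 0.7 + (theta - 1.2)
        assert np.allclose(np.exp(1j * got), np.exp(1j * expect), atol=1e-12)

    @pytest.mark.parametrize("omega", [0.01, 0.1, 0.5, 1.0])
    def test_at_alpha_returns_beta(self, omega):
        assert phase(2.0, alpha=2.0, beta=0.9, omega=omega) == pytest.approx(0.9)

    @pytest.mark.parametrize("omega", [0.02, 0.3, 1.0])
    def test_half_period_offset(self, omega):
        """At theta = alpha + pi the phase takes its limit value beta + pi."""
        got = phase(1.0 + np.pi, alpha=1.0, beta=0.4, omega=omega)
        assert np.exp(1j * got) == pytest.approx(np.exp(1j * (0.4 + np.pi)), abs=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(
        alpha=st.floats(0, TWO_PI - 1e-9),
        beta=st.floats(0, TWO_PI - 1e-9),
        omega=st.floats(0.01, 1.0),
    )
    def test_monotone_over_period(self, alpha, beta, omega):
        """The phase advances by exactly 2*pi per period, monotonically."""
        theta = np.linspace(0, TWO_PI, 400, endpoint=False)
        ph = np.unwrap(phase(theta, alpha, beta, omega))
        assert np.all(np.diff(ph) > 0)
        full = phase(np.array([0.0]), alpha, beta, omega)
        wrap = phase(np.array([TWO_PI - 1e-9]), alpha, beta, omega)
        assert np.exp(1j * (wrap - full)) == pytest.approx(np.exp(-1j * 1e-9), abs=1e-6)

    def test_invalid_omega(self):
        with pytest.raises(ValueError):
            phase(0.0, 0.0, 0.0, 1.5)


class TestWaveValue:
    def test_at_alpha(self):
        w = FMMWave(A=3.0, alpha=1.0, beta=2.0, omega=0.3)
        assert wave_value(1.0, w) == pytest.approx(3.0 * np.cos(2.0))

    def test_amplitude_bound(self):
        w = FMMWave(A=5.0, alpha=0.3, beta=4.0, omega=0.07)
        theta = np.linspace(0, TWO_PI, 2000, endpoint=False)
        assert np.max(np.abs(wave_value(theta, w))) <= 5.0 + 1e-12

    def test_unit_peak(self):
        assert wave_value(0.0, FMMWave(A=1.0, alpha=0.0, beta=0.0, omega=0.2)) == pytest.approx(1.0)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            FMMWave(A=-1.0, alpha=0, beta=0, omega=0.5)
        with pytest.raises(ValueError):
            FMMWave(A=1.0, alpha=0, beta=0, omega=0.0)


class TestRSquared:
    def test_hand_example(self):
        assert r_squared([0, 1, 2, 3], [0, 1, 2, 4]) == pytest.approx(0.8)

    def test_perfect_fit(self):
        y = np.sin(np.linspace(0, 6, 50))
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_baseline(self):
        y = np.array([1.0, 2.0, 3.0, 10.0])
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_constant_observed_raises(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(10), np.ones(10))


class TestFitMono:
    def test_parameter_recovery_noiseless(self):
        true = FMMWave(A=10.0, alpha=1.0, beta=2.0, omega=0.1)
        theta = np.linspace(0, TWO_PI, 200, endpoint=False)
        y = wave_value(theta, true)
        M, w, r2 = fit_mono(y, theta)
        assert r2 > 0.9999
        assert abs(M) < 1e-3
        assert w.A == pytest.approx(10.0, abs=1e-2)
        assert circdist(w.alpha, 1.0) < 1e-3
        assert circdist(w.beta, 2.0) < 1e-3
        assert w.omega == pytest.approx(0.1, abs=1e-3)

    def test_refit_of_fitted_values_is_perfect(self):
        theta = np.linspace(0, TWO_PI, 120, endpoint=False)
        y = 2.0 + wave_value(theta, FMMWave(A=4, alpha=2.5, beta=1.0, omega=0.3))
        M, w, _ = fit_mono(y, theta)
        fitted = M + wave_value(theta, w)
        _, _, r2 = fit_mono(fitted, theta)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_sinusoid_recovers_omega_one(self):
        """A pure cosine is the omega=1 member of the wave family."""
        theta = np.linspace(0, TWO_PI, 150, endpoint=False)
        y = 3.0 * np.cos(theta - 0.8)
        _, w, r2 = fit_mono(y, theta)
        assert r2 > 0.9999
        assert w.omega > 0.98

    def test_constant_signal_raises(self):
        with pytest.raises(ValueError):
            fit_mono(np.ones(50))


class TestFitMulti:
    def test_single_wave_matches_mono(self):
        theta = np.linspace(0, TWO_PI, 150, endpoint=False)
        y = 1.0 + wave_value(theta, FMMWave(A=8, alpha=2.0, beta=3.0, omega=0.15))
        _, _, r2_mono = fit_mono(y, theta)
        model = fit_multi(y, 1, theta)
        assert model.r2 == pytest.approx(r2_mono, abs=1e-6)

    def test_two_wave_recovery_under_noise(self):
        rng = np.random.default_rng(7)
        theta = np.linspace(0, TWO_PI, 400, endpoint=False)
        y = (
            wave_value(theta, FMMWave(A=50, alpha=1.0, beta=2.5, omega=0.05))
            + wave_value(theta, FMMWave(A=15, alpha=3.5, beta=4.5, omega=0.2))
            + rng.normal(0, 1.0, 400)
        )
        model = fit_multi(y, 2, theta)
        amps = sorted([w.A for w in model.waves], reverse=True)
        assert amps[0] == pytest.approx(50, rel=0.10)
        assert amps[1] == pytest.approx(15, rel=0.10)

    def test_r2_monotone_in_wave_count(self):
        rng = np.random.default_rng(3)
        theta = np.linspace(0, TWO_PI, 300, endpoint=False)
        y = (
            wave_value(theta, FMMWave(A=10, alpha=0.7, beta=1.0, omega=0.1))
            + np.cos(2 * theta)
            + rng.normal(0, 0.5, 300)
        )
        r2s = [fit_multi(y, m, theta).r2 for m in (1, 2, 3)]
        assert r2s[0] <= r2s[1] + 1e-9
        assert r2s[1] <= r2s[2] + 1e-9

    def test_excessive_wave_count_raises(self):
        with pytest.raises(ValueError):
            fit_multi(np.sin(np.linspace(0, 6, 40)), 11)


class TestTimeGrid:
    def test_sixty_ms_grid(self):
        """A 60 ms record at dt=0.05 maps to 1200 angles covering [0, 2*pi)."""
        t = np.arange(0, 60, 0.05)
        grid = TimeGrid.from_times(t)
        assert grid.theta.size == 1200
        assert grid.theta[0] == 0.0
        assert grid.theta[-1] < TWO_PI
        assert np.allclose(np.diff(grid.theta), TWO_PI / 1200)

    def test_rejects_non_monotone(self):
        with pytest.raises(ValueError):
            TimeGrid.from_times(np.array([0.0, 1.0, 0.5]))
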