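"""Spike detection, restricted spike-train fitting, distances and features."""

import math

import numpy as np
import pytest

from fmmst.hh import HHParameters, StimulusProtocol, simulate
from fmmst.spiketrain import (
    DetectionConfig,
    detect_spikes,
    extract_features,
    fit_st,
    fit_variants,
    free_param_count,
    wave_distances,
)
from fmmst.synth import default_spec, generate_train
from fmmst.waves import TimeGrid

from conftest import make_spec


def circdist(a, b):
    return np.abs(np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b)))))


class TestDetectSpikes:
    def test_constant_signal(self):
        s, peaks = detect_spikes(np.full(100, 3.0))
        assert s == 0 and peaks.size == 0

    def test_noiseless_synthetic_train(self):
        theta, y = generate_train(default_spec(s=4))
        s, _ = detect_spikes(y)
        assert s == 4

    @pytest.mark.parametrize("s_true", [1, 2, 3, 5, 6])
    def test_recovers_generating_count(self, s_true):
        """With the resting level (median) as reference the generating
        spike count is recovered; on dense trains the raw mean sits too
        high to serve as the height reference."""
        theta, y = generate_train(default_spec(s=s_true))
        s, _ = detect_spikes(y, baseline=np.median(y))
        assert s == s_true

    def test_single_hh_action_potential(self):
        traj = simulate(HHParameters(), StimulusProtocol(amplitude=12.0))
        s, peaks = detect_spikes(traj.X, t=traj.t, baseline=traj.resting_value)
        assert s == 1
        assert traj.X[peaks[0]] > 0

    def test_subthreshold_response_not_counted(self):
        """A few-mV ringing response is not an action potential."""
        t = np.arange(0, 60, 0.05)
        y = -65.0 + 4.0 * np.exp(-(t - 12) ** 2 / 4.0)
        s, _ = detect_spikes(y, t=t, baseline=-65.0)
        assert s == 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectionConfig(k_factor=0)
        with pytest.raises(ValueError):
            DetectionConfig(refractory=-1)


class TestFreeParamCount:
    @pytest.mark.parametrize(
        "variant,s,expected",
        [("ST", 4, 21), ("ST*", 4, 15), ("s*", 4, 11), ("s**", 4, 8), ("ST", 1, 9)],
    )
    def test_counting_rule(self, variant, s, expected):
        assert free_param_count(variant, s) == expected

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            free_param_count("full", 2)

    def test_invalid_s(self):
        with pytest.raises(ValueError):
            free_param_count("ST", 0)


class TestWaveDistances:
    def test_coincident_waves_have_zero_distance(self):
        spec = default_spec(s=2)
        model = spec.to_model()
        model.alpha_B = model.alpha_A.copy()
        d_ab, _ = wave_distances(model)
        assert np.allclose(d_ab, 0.0)

    def test_antipodal_spikes(self):
        spec = default_spec(s=2)
        model = spec.to_model()
        model.alpha_A = np.array([0.5, 0.5 + np.pi])
        _, d_ap = wave_distances(model)
        assert d_ap[0] == pytest.approx(2.0)

    def test_single_spike_has_no_ap_distance(self):
        model = default_spec(s=1).to_model()
        d_ab, d_ap = wave_distances(model)
        assert d_ap.size == 0 and d_ab.size == 1

    def test_range(self):
        model = default_spec(s=5).to_model()
        d_ab, d_ap = wave_distances(model)
        for d in (d_ab, d_ap):
            assert np.all((d >= 0) & (d <= 2))


class TestExtractFeatures:
    def test_identical_spikes_yield_common_values(self):
        spec = default_spec(s=3)
        model = spec.to_model()
        model.A_A = np.full(3, 50.0)
        model.A_B = np.full(3, 15.0)
        f = extract_features(model)
        assert f.AmA == pytest.approx(50.0)
        assert f.AmB == pytest.approx(15.0)
        assert f.s == 3

    def test_single_spike_missing_ap_distance(self):
        f = extract_features(default_spec(s=1).to_model())
        assert math.isnan(f.dmAP)

    def test_beta_b_expansion(self):
        model = default_spec(s=2).to_model()
        model.beta_B = 1.5 * np.pi
        f = extract_features(model)
        assert f.cosBetaB == pytest.approx(0.0, abs=1e-12)
        assert f.sinBetaB == pytest.approx(-1.0)


class TestFitST:
    def test_three_spike_recovery(self, three_spike_spec):
        """Amplitudes, locations and shapes recovered from a noisy train."""
        spec = three_spike_spec
        theta, y = generate_train(spec)
        model = fit_st(y, s=3, variant="ST", theta=theta)
        assert model.r2 > 0.98
        assert np.allclose(np.sort(model.A_A), np.sort(spec.A_A), rtol=0.10)
        assert np.allclose(np.sort(model.A_B), np.sort(spec.A_B), rtol=0.10)
        assert np.all(circdist(np.sort(model.alpha_A), np.sort(spec.alpha_A)) < 0.05)
        assert abs(model.omega_A - spec.omega_A) < 0.01
        assert circdist(model.beta_A, spec.beta_A) < 0.05

    def test_noiseless_round_trip(self, noiseless_signal):
        spec, theta, y = noiseless_signal
        model = fit_st(y, s=spec.s, variant="ST", theta=theta)
        assert model.r2 > 0.9999

    def test_shared_shape_by_construction(self, noiseless_signal):
        """Under every variant the per-spike waveforms share beta and omega."""
        spec, theta, y = noiseless_signal
        model = fit_st(y, s=spec.s, variant="ST", theta=theta)
        betas = {w.beta for w in model.waves_a()}
        omegas = {w.omega for w in model.waves_a()}
        assert len(betas) == 1 and len(omegas) == 1

    def test_dominance_and_ordering(self, noiseless_signal):
        spec, theta, y = noiseless_signal
        model = fit_st(y, s=spec.s, variant="ST", theta=theta)
        assert model.dominance_ok
        assert np.all(model.A_A >= model.A_B - 1e-9)
        assert np.all(np.diff(model.alpha_A) > 0)

    def test_single_spike_matches_bicomponent_fit(self):
        """With one spike the ST model is a two-wave FMM decomposition."""
        from fmmst.waves import fit_multi

        spec = default_spec(s=1, sigma=0.5, seed=3)
        theta, y = generate_train(spec)
        st_model = fit_st(y, s=1, variant="ST", theta=theta)
        multi = fit_multi(y, 2, theta)
        assert st_model.r2 == pytest.approx(multi.r2, abs=0.02)
        assert st_model.r2 > 0.99

    def test_equal_amplitude_variants(self, noiseless_signal):
        spec, theta, y = noiseless_signal
        st_star = fit_st(y, s=spec.s, variant="ST*", theta=theta)
        assert np.allclose(st_star.A_A, st_star.A_A[0])
        assert np.allclose(st_star.A_B, st_star.A_B[0])
        s_star2 = fit_st(y, s=spec.s, variant="s**", theta=theta)
        assert not s_star2.has_b_waves
        assert np.allclose(s_star2.A_A, s_star2.A_A[0])

    def test_restriction_lattice_monotonicity(self, noiseless_signal):
        spec, theta, y = noiseless_signal
        fits = fit_variants(y, s=spec.s, variants=("s**", "s*", "ST*", "ST"), theta=theta)
        assert fits["s**"].r2 <= fits["s*"].r2 + 1e-9
        assert fits["s*"].r2 <= fits["ST*"].r2 + 1e-9
        assert fits["ST*"].r2 <= fits["ST"].r2 + 1e-9

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            fit_st(np.sin(np.linspace(0, 6.2, 30)), s=3, variant="ST")

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError):
            fit_st(np.sin(np.linspace(0, 6.2, 100)), s=1, variant="XX")


class TestParameterRecoveryStudy:
    def test_median_errors_over_synthetic_trains(self):
        """Median recovery errors over 50 trains: amplitudes < 5 %,
        locations < 0.03 rad, kurtosis < 0.01 (noise sd = 2 % of A^A)."""
        rng = np.random.default_rng(2024)
        amp_err, loc_err, om_err = [], [], []
        for i in range(50):
            s = int(rng.choice([2, 3, 4]))
            spec = make_spec(s, sigma=0.02 * 50.0, seed=i, rng=rng)
            theta, y = generate_train(spec)
            model = fit_st(y, s=s, variant="ST", theta=theta)
            order_true = np.argsort(spec.alpha_A)
            a_true = np.asarray(spec.A_A)[order_true]
            al_true = np.sort(np.asarray(spec.alpha_A))
            amp_err.append(np.max(np.abs(model.A_A - a_true) / a_true))
            loc_err.append(np.max(circdist(model.alpha_A, al_true)))
            om_err.append(abs(model.omega_A - spec.omega_A))
        assert np.median(amp_err) < 0.05
        assert np.median(loc_err) < 0.03
        assert np.median(om_err) < 0.01
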