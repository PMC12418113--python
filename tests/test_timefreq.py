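"""Time-frequency module: wavelet localisation, the evoked/induced
decomposition and its closed-form limits, baseline normalisation, and
peak detection."""
import numpy as np
import pytest

from conftest import make_epochs
from thetareset import (BaselineSpec, SimulationConfig, baseline_normalize,
                        decompose_evoked_induced, find_peak, morlet_transform,
                        simulate_epoch_set, single_trial_band_power)
from thetareset.timefreq import find_subject_peak_frequency

FS = 250.0


def sine_epochs(freq, n_trials=3, n_time=1024, phases=None, amp=1.0):
    t = np.arange(n_time) / FS
    phases = np.zeros(n_trials) if phases is None else phases
    data = amp * np.cos(2 * np.pi * freq * t[None, :] + phases[:, None])
    return make_epochs(data)


class TestMorletTransform:
    def test_pure_tone_power_peaks_at_its_frequency(self):
        eps = sine_epochs(8.0)
        spec = morlet_transform(eps, 0, np.arange(1.0, 21.0),
                                trim=(-500, 500))
        mean_power = spec.power_single_trial.mean(axis=(0, 2))
        assert spec.freqs[np.argmax(mean_power)] == 8.0

    def test_dc_input_has_no_oscillatory_power(self):
        dc = make_epochs(np.ones((3, 1024)))
        tone = sine_epochs(8.0)
        freqs = np.arange(4.0, 21.0)
        p_dc = morlet_transform(dc, 0, freqs, trim=(-500, 500)
                                ).power_single_trial.max()
        p_tone = morlet_transform(tone, 0, freqs, trim=(-500, 500)
                                  ).power_single_trial.max()
        assert p_dc < 1e-6 * p_tone

    def test_two_tone_magnitudes_match_fft_oracle(self):
        """6 + 12 Hz mixture: local maxima at both tones, and the power
        ratio between them matches a rectangular-window FFT oracle."""
        t = np.arange(2048) / FS
        a6, a12 = 1.0, 0.6
        data = (a6 * np.cos(2 * np.pi * 6 * t)
                + a12 * np.cos(2 * np.pi * 12 * t))[None, :]
        eps = make_epochs(data)
        spec = morlet_transform(eps, 0, np.arange(2.0, 21.0),
                                trim=(-1000, 1000))
        mean_p = spec.power_single_trial.mean(axis=(0, 2))
        i6 = int(np.where(spec.freqs == 6.0)[0][0])
        i12 = int(np.where(spec.freqs == 12.0)[0][0])
        assert mean_p[i6] > mean_p[i6 - 1] and mean_p[i6] > mean_p[i6 + 1]
        assert mean_p[i12] > mean_p[i12 - 1] and mean_p[i12] > mean_p[i12 + 1]
        # FFT oracle on an integer number of cycles of both tones
        seg = data[0, :2000]                     # 8 s: whole cycles of 6 & 12
        amp = np.abs(np.fft.rfft(seg)) / len(seg) * 2
        f_axis = np.fft.rfftfreq(len(seg), 1 / FS)
        fft_ratio = (amp[f_axis == 6.0][0] / amp[f_axis == 12.0][0]) ** 2
        morlet_ratio = mean_p[i6] / mean_p[i12]
        assert morlet_ratio == pytest.approx(fft_ratio, rel=0.05)

    def test_edge_flags_mark_frequencies_with_insufficient_guard(self):
        eps = sine_epochs(8.0, n_time=600)       # only 2.4 s of data
        spec = morlet_transform(eps, 0, np.array([2.0, 20.0]),
                                trim=(-400, 400))
        assert spec.edge_flags[0] and not spec.edge_flags[1]


class TestEvokedInduced:
    def test_identical_trials_are_fully_evoked(self):
        eps = sine_epochs(8.0, n_trials=20)
        spec = morlet_transform(eps, 0, np.array([8.0]), trim=(-500, 500))
        spec = decompose_evoked_induced(spec, eps, 0)
        assert np.max(np.abs(spec.power_induced)) < 1e-10 * spec.power_total.max()
        assert np.allclose(spec.power_evoked, spec.power_total)

    def test_random_phases_are_fully_induced(self, rng):
        n = 2000
        eps = sine_epochs(8.0, n_trials=n,
                          phases=rng.uniform(-np.pi, np.pi, n))
        spec = morlet_transform(eps, 0, np.array([8.0]), trim=(-500, 500))
        spec = decompose_evoked_induced(spec, eps, 0)
        mid = spec.power_total.shape[1] // 2
        assert spec.power_evoked[0, mid] < 2.0 / n * spec.power_total[0, mid]

    def test_half_locked_mixture_matches_mean_field_oracle(self, rng):
        """50% fixed-phase / 50% random trials: the evoked/total ratio
        equals |mean field|^2 = 0.25 up to the 1/N sampling term."""
        n = 2000
        phases = np.where(np.arange(n) < n // 2, 0.0,
                          rng.uniform(-np.pi, np.pi, n))
        eps = sine_epochs(8.0, n_trials=n, phases=phases)
        spec = morlet_transform(eps, 0, np.array([8.0]), trim=(-500, 500))
        spec = decompose_evoked_induced(spec, eps, 0)
        mid = spec.power_total.shape[1] // 2
        ratio = spec.power_evoked[0, mid] / spec.power_total[0, mid]
        assert ratio == pytest.approx(0.25, abs=0.02)

    def test_energy_identity_holds_exactly(self, reset_epochs):
        spec = morlet_transform(reset_epochs, "right_posterior",
                                np.arange(4.0, 13.0))
        spec = decompose_evoked_induced(spec, reset_epochs, "right_posterior")
        resid = spec.power_total - spec.power_evoked - spec.power_induced
        assert np.max(np.abs(resid)) == 0.0
        assert spec.power_induced.min() >= 0.0

    def test_single_trial_rejected(self):
        eps = sine_epochs(8.0, n_trials=1)
        spec = morlet_transform(eps, 0, np.array([8.0]), trim=(-500, 500))
        with pytest.raises(ValueError, match="2 trials"):
            decompose_evoked_induced(spec, eps, 0)


class TestBaselineNormalize:
    T = np.arange(-250.0, 1000.0, 4.0)

    def test_stationary_power_maps_to_zero(self):
        power = np.full((3, len(self.T)), 5.0)
        out = baseline_normalize(power, BaselineSpec(), self.T)
        assert np.allclose(out, 0.0)

    def test_doubling_maps_to_one(self):
        power = np.full((2, len(self.T)), 1.0)
        power[:, self.T > 0] = 2.0
        out = baseline_normalize(power, BaselineSpec(), self.T)
        assert np.allclose(out[:, self.T > 0], 1.0)

    def test_linear_ramp_is_recovered_exactly(self):
        """Power B(1 + t/T) with a pre-event plateau maps to t/T."""
        T_scale = 500.0
        ramp = np.where(self.T > 0, self.T / T_scale, 0.0)
        power = 3.0 * (1.0 + ramp)[None, :]
        out = baseline_normalize(power, BaselineSpec(), self.T)
        assert np.allclose(out[0], ramp)

    def test_nonpositive_baseline_yields_nan_not_inf(self):
        power = np.zeros((2, len(self.T)))
        power[1] = 1.0
        out = baseline_normalize(power, BaselineSpec(), self.T)
        assert np.isnan(out[0]).all()
        assert np.isfinite(out[1]).all()

    def test_scaling_invariance(self, reset_epochs):
        spec = morlet_transform(reset_epochs, 0, np.arange(6.0, 10.0))
        p = spec.power_single_trial.mean(axis=0)
        n1 = baseline_normalize(p, BaselineSpec(), spec.time_axis)
        n2 = baseline_normalize(9.0 * p, BaselineSpec(), spec.time_axis)
        assert np.allclose(n1, n2)


class TestFindPeak:
    FREQS = np.arange(4.0, 13.0)
    T = np.arange(-100.0, 600.0, 4.0)

    def _grid(self):
        return np.zeros((len(self.FREQS), len(self.T)))

    def test_gaussian_bump_located_exactly(self):
        g = self._grid()
        ff, tt = np.meshgrid(self.FREQS, self.T, indexing="ij")
        g += np.exp(-((tt - 200) / 80.0) ** 2 - ((ff - 8) / 1.5) ** 2)
        peak = find_peak(g, self.FREQS, self.T, (4, 12), (0, 600))
        assert peak.peak_latency == 200.0
        assert peak.peak_frequency == 8.0

    def test_ties_break_to_earliest_latency_then_lowest_frequency(self):
        g = self._grid()
        g[2, self.T == 300.0] = 1.0
        g[2, self.T == 152.0] = 1.0
        g[4, self.T == 152.0] = 1.0
        peak = find_peak(g, self.FREQS, self.T, (4, 12), (0, 600))
        assert peak.peak_latency == 152.0
        assert peak.peak_frequency == self.FREQS[2]

    def test_empty_subgrid_rejected(self):
        with pytest.raises(ValueError):
            find_peak(self._grid(), self.FREQS, self.T, (20, 30), (0, 600))


class TestSingleTrialBandPower:
    def test_identical_trials_have_zero_variance(self):
        eps = sine_epochs(8.0, n_trials=10)
        spec = morlet_transform(eps, 0, np.arange(5.0, 11.0),
                                trim=(-500, 500))
        spec.time_axis = spec.time_axis  # times span -500..500 here
        table = single_trial_band_power(
            spec, [(7, 8)], window=(50, 250),
            baseline=BaselineSpec((-200, -100)))
        assert table["7-8"].std() == pytest.approx(0.0, abs=1e-12)

    def test_band_power_tracks_squared_amplitude(self):
        """With per-trial log-normal amplitudes and no noise, band power is
        an affine function of amplitude^2 (correlation ~ 1)."""
        cfg = SimulationConfig(
            n_subjects=1, n_trials_per_condition=40, include_nomaze=False,
            mechanism="none", noise_1f_amp=0.0, noise_white_amp=0.0,
            freq_jitter_sd=0.0, amplitude_trial_sigma=0.5, seed=3)
        eps = simulate_epoch_set(cfg)
        spec = morlet_transform(eps, "right_posterior", np.arange(5.0, 11.0))
        table = single_trial_band_power(spec, [(7, 9)], window=(-100, 100))
        amp2 = eps.ground_truth["amplitude"].to_numpy() ** 2
        r = np.corrcoef(amp2, table["7-9"])[0, 1]
        assert r > 0.95


def test_subject_peak_frequency_identifies_carrier(reset_epochs):
    spec = morlet_transform(reset_epochs, "right_posterior",
                            np.arange(4.0, 13.0))
    assert find_subject_peak_frequency(spec) == 8.0
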