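"""Signal-chain unit and property tests: re-referencing, filtering,
artifact masking, Welch spectra, alpha power and the FAA index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from faakit.eeg import (
    AlphaPower,
    EEGRecording,
    SpectralEstimate,
    alpha_band_power,
    bandpass,
    compute_faa,
    faa_from_recording,
    reject_artifacts,
    rereference_common_average,
    welch_psd,
)
from faakit.synthetic import EEGSynthesisSpec, generate_eeg

from conftest import sinusoid_recording


def _steady_amplitude(x, fs, freq, discard_s=2.0):
    """Amplitude of the ``freq`` component via quadrature projection on the
    central portion (excludes filter edge transients and slow drift)."""
    edge = int(discard_s * fs)
    seg = x[edge:-edge]
    t = np.arange(seg.size) / fs
    if freq == 0.0:
        return abs(seg.mean())
    c = 2 * np.mean(seg * np.cos(2 * np.pi * freq * t))
    s = 2 * np.mean(seg * np.sin(2 * np.pi * freq * t))
    return float(np.hypot(c, s))


# ------------------------------------------------------------------- CAR --

class TestCommonAverageReference:
    def test_toy_matrix_matches_per_sample_mean_subtraction(self):
        x = np.array([[1.0, 2, 3, 4], [5, 6, 7, 8], [0, 0, 12, 0]])
        rec = EEGRecording(samples=x, fs=100, channel_labels=["F3", "F4", "Cz"])
        out = rereference_common_average(rec)
        expected = x - x.mean(axis=0)  # brute-force per-sample mean subtraction
        np.testing.assert_allclose(out.samples, expected, atol=1e-12)
        assert np.abs(out.samples.mean(axis=0)).max() < 1e-9

    def test_constant_channels_become_zero(self):
        rec = EEGRecording(samples=np.full((3, 50), 3.7), fs=100,
                           channel_labels=["F3", "F4", "Cz"])
        out = rereference_common_average(rec)
        assert np.abs(out.samples).max() < 1e-12

    def test_idempotent(self, clean_recording):
        spec = EEGSynthesisSpec(target_faa=0.1, duration_s=5, n_extra_channels=3,
                                seed=0)
        rec = generate_eeg(spec)
        once = rereference_common_average(rec)
        twice = rereference_common_average(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-9)

    def test_aux_channels_excluded_from_average(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 200))
        x[3] += 500.0  # big EOG offset must not leak into the scalp average
        rec = EEGRecording(samples=x, fs=100,
                           channel_labels=["F3", "F4", "Cz", "VEOG"])
        out = rereference_common_average(rec)
        scalp_mean = out.samples[:3].mean(axis=0)
        assert np.abs(scalp_mean).max() < 1e-9

    def test_single_scalp_channel_errors(self):
        rec = EEGRecording(samples=np.zeros((2, 10)), fs=100,
                           channel_labels=["F3", "VEOG"])
        with pytest.raises(ValueError, match="2 scalp channels"):
            rereference_common_average(rec)


# -------------------------------------------------------------- bandpass --

class TestBandpass:
    @pytest.mark.parametrize("freq,amp_range", [
        (10.0, (0.99, 1.01)),   # passband identity
        (60.0, (0.0, 0.05)),    # stopband above 40 Hz
    ])
    def test_frequency_response(self, freq, amp_range):
        rec = sinusoid_recording(freq, fs=500, duration_s=12)
        out = bandpass(rec)
        amp = _steady_amplitude(out.samples[0], rec.fs, freq)
        assert amp_range[0] <= amp <= amp_range[1]

    def test_dc_removed(self):
        rec = EEGRecording(samples=np.full((1, 6000), 5.0), fs=500,
                           channel_labels=["F3"])
        out = bandpass(rec)
        assert _steady_amplitude(out.samples[0], 500, 0.0, discard_s=4.0) <= 0.05 * 5.0

    def test_band_outside_nyquist_errors(self):
        rec = sinusoid_recording(10, fs=100)
        with pytest.raises(ValueError, match="fs/2"):
            bandpass(rec, low=0.3, high=60.0)


# ---------------------------------------------------------- artifact mask --

class TestRejectArtifacts:
    def test_clean_sinusoid_has_empty_mask(self):
        rec = sinusoid_recording(10, fs=500, duration_s=10)
        out = reject_artifacts(rec, z_threshold=8.0, pad_s=0.2)
        assert not out.artifact_mask.any()

    def test_burst_masked_with_padding(self):
        fs = 500.0
        rec = sinusoid_recording(10, fs=fs, duration_s=20, amp=10.0)
        x = rec.samples.copy()
        start, width = 5000, 100
        x[0, start:start + width] += 500.0
        rec = EEGRecording(samples=x, fs=fs, channel_labels=["F3"])
        out = reject_artifacts(rec, z_threshold=6.0, pad_s=0.2)
        pad = int(0.2 * fs)
        assert out.artifact_mask[start:start + width].all()
        assert out.artifact_mask[start - pad + 1:start].all()
        assert out.artifact_mask[start + width:start + width + pad - 1].all()
        # far away from the burst stays clean
        assert not out.artifact_mask[: start - 2 * pad].any()

    def test_all_masked_errors(self):
        fs = 100.0
        x = np.sin(2 * np.pi * 10 * np.arange(200) / fs)
        x[100] = 1e5
        rec = EEGRecording(samples=x[None, :], fs=fs, channel_labels=["F3"])
        with pytest.raises(ValueError, match="no clean data"):
            reject_artifacts(rec, z_threshold=6.0, pad_s=10.0)

    def test_rejection_recovers_faa_under_blinks(self):
        """Median |FAA error| over paired seeds must shrink with rejection."""
        target = 0.0891
        err_with, err_without = [], []
        for seed in range(50):
            spec = EEGSynthesisSpec(target_faa=target, duration_s=30,
                                    noise_sd=0.5, blink_rate=8.0,
                                    artifact_rate=0.0, seed=seed)
            rec = generate_eeg(spec)
            filt = bandpass(rec)
            psd_raw = welch_psd(filt)
            faa_raw = compute_faa(AlphaPower(
                p_f3=alpha_band_power(psd_raw, "F3"),
                p_f4=alpha_band_power(psd_raw, "F4"))).ratio
            masked = reject_artifacts(filt, z_threshold=6.0, pad_s=0.2)
            psd_clean = welch_psd(masked)
            faa_clean = compute_faa(AlphaPower(
                p_f3=alpha_band_power(psd_clean, "F3"),
                p_f4=alpha_band_power(psd_clean, "F4"))).ratio
            err_without.append(abs(faa_raw - target))
            err_with.append(abs(faa_clean - target))
        assert np.median(err_with) < np.median(err_without)


# ------------------------------------------------------------------ Welch --

class TestWelchPSD:
    def test_parseval_sinusoid(self):
        rec = sinusoid_recording(10, fs=500, duration_s=20)
        spec = welch_psd(rec)
        sel = (spec.freqs >= 8) & (spec.freqs <= 13)
        band_power = np.trapezoid(spec.psd[0][sel], spec.freqs[sel])
        assert abs(band_power - 0.5) < 0.05 * 0.5

    def test_matches_scipy_welch_unmasked(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 5000))
        rec = EEGRecording(samples=x, fs=500, channel_labels=["F3", "F4"])
        spec = welch_psd(rec, window_s=2.0, overlap=0.5)
        f_ref, p_ref = sps.welch(x, fs=500, window="hann", nperseg=1000,
                                 noverlap=500, detrend=False, axis=1)
        np.testing.assert_allclose(spec.freqs, f_ref, atol=1e-12)
        np.testing.assert_allclose(spec.psd, p_ref, rtol=1e-9)

    def test_masked_windows_dropped(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1, 5000))
        mask = np.zeros(5000, bool)
        mask[1200:1300] = True
        rec = EEGRecording(samples=x, fs=500, channel_labels=["F3"],
                           artifact_mask=mask)
        spec = welch_psd(rec, window_s=2.0, overlap=0.5)
        # windows at starts 500 and 1000 overlap the mask; 0, 1500, ... survive
        assert spec.method_params["n_windows"] == 7

    def test_zero_signal_zero_psd(self):
        rec = EEGRecording(samples=np.zeros((1, 4000)), fs=500,
                           channel_labels=["F3"])
        spec = welch_psd(rec)
        assert np.abs(spec.psd).max() == 0.0

    def test_split_half_stability_white_noise(self):
        """Log-PSDs of disjoint halves agree (KS p > .01) in >= 95% of seeds."""
        from scipy.stats import ks_2samp
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(20000)
            halves = []
            for h in (x[:10000], x[10000:]):
                rec = EEGRecording(samples=h[None, :], fs=500,
                                   channel_labels=["F3"])
                halves.append(np.log(welch_psd(rec).psd[0][1:]))
            if ks_2samp(halves[0], halves[1]).pvalue > 0.01:
                ok += 1
        assert ok >= 0.95 * n_seeds

    def test_insufficient_data_errors(self):
        rec = EEGRecording(samples=np.zeros((1, 500)), fs=500,
                           channel_labels=["F3"])
        with pytest.raises(ValueError, match="insufficient clean data"):
            welch_psd(rec, window_s=2.0)


# ------------------------------------------------------------ alpha power --

class TestAlphaBandPower:
    def _spec(self, freqs, psd):
        return SpectralEstimate(freqs=np.asarray(freqs),
                                psd=np.asarray(psd)[None, :],
                                channel_labels=["F3"])

    def test_constant_spectrum_returns_constant(self):
        freqs = np.arange(0, 50.5, 0.5)
        spec = self._spec(freqs, np.full(freqs.size, 2.5))
        assert alpha_band_power(spec, "F3") == pytest.approx(2.5)

    def test_single_hot_bin_toy_grid(self):
        freqs = np.array([8.0, 9.0, 10.0, 11.0, 12.0, 13.0])  # 6 in-band points
        psd = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])
        assert alpha_band_power(self._spec(freqs, psd), "F3") == pytest.approx(1 / 6)

    def test_band_edges_inclusive(self):
        freqs = np.array([7.5, 8.0, 13.0, 13.5])
        psd = np.array([9.0, 1.0, 3.0, 9.0])
        assert alpha_band_power(self._spec(freqs, psd), "F3") == pytest.approx(2.0)

    def test_band_outside_grid_errors(self):
        spec = self._spec(np.array([20.0, 25.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="band"):
            alpha_band_power(spec, "F3")

    def test_missing_channel_errors(self):
        spec = self._spec(np.array([8.0, 13.0]), np.array([1.0, 1.0]))
        with pytest.raises(KeyError):
            alpha_band_power(spec, "F4")


# -------------------------------------------------------------------- FAA --

class TestComputeFAA:
    def test_symmetric_powers_zero(self):
        faa = compute_faa(AlphaPower(p_f3=5.0, p_f4=5.0))
        assert faa.ratio == 0.0 and faa.reported == 0.0

    def test_direct_substitution(self):
        assert compute_faa(AlphaPower(p_f3=1.0, p_f4=2.0)).ratio == pytest.approx(1 / 3)

    def test_zero_total_power_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_faa(AlphaPower(p_f3=0.0, p_f4=0.0))

    @given(a=st.floats(0, 1e6), b=st.floats(0, 1e6))
    @settings(derandomize=True, max_examples=200)
    def test_antisymmetry_and_bounds(self, a, b):
        if a + b == 0:
            return
        fwd = compute_faa(AlphaPower(p_f3=a, p_f4=b)).ratio
        rev = compute_faa(AlphaPower(p_f3=b, p_f4=a)).ratio
        assert fwd == -rev
        assert -1.0 <= fwd <= 1.0
        if min(a, b) == 0.0:
            assert abs(fwd) == 1.0
        elif min(a, b) / max(a, b) > 1e-15:  # above float resolution
            assert abs(fwd) < 1.0

    @given(a=st.floats(1e-3, 1e3), b=st.floats(1e-3, 1e3),
           k=st.floats(1e-3, 1e3))
    @settings(derandomize=True, max_examples=100)
    def test_scale_invariance(self, a, b, k):
        base = compute_faa(AlphaPower(p_f3=a, p_f4=b)).ratio
        scaled = compute_faa(AlphaPower(p_f3=k * a, p_f4=k * b)).ratio
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_reported_scale_is_1000x(self):
        faa = compute_faa(AlphaPower(p_f3=1.0, p_f4=3.0))
        assert faa.reported == 1000.0 * faa.ratio


class TestEndToEnd:
    def test_symmetric_noise_free_recording_gives_zero_faa(self):
        spec = EEGSynthesisSpec(target_faa=0.0, duration_s=20, noise_sd=0.0,
                                blink_rate=0.0, artifact_rate=0.0, seed=5)
        res = faa_from_recording(generate_eeg(spec))
        assert abs(res["faa_ratio"]) < 1e-9

    def test_roundtrip_noise_free_exact(self, clean_recording):
        res = faa_from_recording(clean_recording)
        assert res["faa_ratio"] == pytest.approx(0.2, abs=1e-6)

    def test_roundtrip_reference_scale(self):
        spec = EEGSynthesisSpec(target_faa=0.0891, duration_s=240,
                                noise_sd=0.2, blink_rate=1.0,
                                artifact_rate=0.2, seed=11)
        res = faa_from_recording(generate_eeg(spec))
        assert res["faa_reported"] == pytest.approx(89.1, abs=5.0)
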