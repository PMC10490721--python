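"""Spatial filtering: STFT identities, steering delays, coherent-sum
gain, MVDR constraints and null steering, and the edge-interval SNR
estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyspnea_hri import beamform
from dyspnea_hri._dsp import fractional_delay
from dyspnea_hri.config import ArrayGeometry


class _Cap:
    def __init__(self, channels, rate, doa_track=None):
        self.channels = np.atleast_2d(channels)
        self.rate = rate
        self.doa_track = doa_track


class TestSTFT:
    def test_512_point_dft_gives_257_bins(self, rng):
        fr = beamform.stft(rng.standard_normal(8000), 16000, frame_length=512, dft_size=512)
        assert fr.num_freq_bins == 257

    def test_round_trip_white_noise(self, rng):
        x = rng.standard_normal(16000)
        fr = beamform.stft(x[None], 16000)
        y = beamform.istft(fr)
        valid = slice(fr.frame_length, len(y) - fr.frame_length)
        err = np.max(np.abs(y[valid] - x[valid])) / np.max(np.abs(x))
        assert err < 1e-6

    def test_tone_energy_in_matching_bin(self):
        fs, f = 16000, 1000.0
        x = np.sin(2 * np.pi * f * np.arange(fs) / fs)
        fr = beamform.stft(x[None], fs, frame_length=512, dft_size=512)
        power = np.mean(np.abs(fr.x[0]) ** 2, axis=0)
        expected_bin = int(round(f * 512 / fs))
        assert abs(int(np.argmax(power)) - expected_bin) <= 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            beamform.stft(np.array([]), 16000)


class TestDelays:
    def test_zero_doa_all_zero(self, geometry):
        np.testing.assert_array_equal(beamform.das_delays(geometry, 0.0), np.zeros(4))

    def test_broadside_end_mic_delay(self, geometry):
        # d=0.12 m, v=343 m/s, phi=90 deg -> 0.12/343 s
        taus = beamform.das_delays(geometry, 90.0)
        assert taus[3] == pytest.approx(0.12 / 343, rel=1e-9)
        assert taus[0] == 0.0

    @given(phi=st.floats(-90, 90))
    @settings(max_examples=50, deadline=None)
    def test_odd_in_doa(self, phi):
        g = ArrayGeometry()
        np.testing.assert_allclose(
            beamform.das_delays(g, -phi), -beamform.das_delays(g, phi), atol=1e-15
        )

    def test_out_of_range_doa_rejected(self, geometry):
        with pytest.raises(ValueError):
            beamform.das_delays(geometry, 120.0)


class TestDelayAndSum:
    def test_identical_aligned_channels_sum_to_four_x(self, geometry, rng):
        x = rng.standard_normal(4000)
        cap = _Cap(np.tile(x, (4, 1)), 16000)
        y = beamform.delay_and_sum(cap, 0.0, geometry)
        np.testing.assert_allclose(y, 4 * x, atol=1e-6)

    def test_coherent_gain_near_6db(self, geometry, rng):
        # plane-wave tone + independent white noise: SNR gain ~ 10 log10(4)
        fs, n, phi = 16000, 2 * 16000, 25.0
        s = np.sin(2 * np.pi * 440 * np.arange(n) / fs)
        taus = beamform.das_delays(geometry, phi) * fs
        clean = np.stack([fractional_delay(s, -t) for t in taus])
        noise = 0.5 * rng.standard_normal(clean.shape)
        ys = beamform.delay_and_sum(_Cap(clean, fs), phi, geometry)
        yn = beamform.delay_and_sum(_Cap(noise, fs), phi, geometry)
        gain = 10 * np.log10(np.sum(ys**2) / np.sum(yn**2)) - 10 * np.log10(
            np.sum(clean[0] ** 2) / np.sum(noise[0] ** 2)
        )
        assert gain == pytest.approx(10 * np.log10(4), abs=0.7)

    def test_missteered_output_weaker_at_tone(self, geometry):
        fs, n, phi = 16000, 16000, 40.0
        s = np.sin(2 * np.pi * 2000 * np.arange(n) / fs)
        taus = beamform.das_delays(geometry, phi) * fs
        clean = np.stack([fractional_delay(s, -t) for t in taus])
        on = beamform.delay_and_sum(_Cap(clean, fs), phi, geometry)
        off = beamform.delay_and_sum(_Cap(clean, fs), -40.0, geometry)
        assert np.sum(off**2) < np.sum(on**2)

    def test_missing_doa_rejected(self, geometry, rng):
        cap = _Cap(rng.standard_normal((4, 100)), 16000)
        with pytest.raises(ValueError):
            beamform.delay_and_sum(cap, None, geometry)


class TestNoiseCovariance:
    def test_spatially_white_noise_gives_scaled_identity(self, rng):
        fs = 16000
        x = rng.standard_normal((4, fs * 2))
        fr = beamform.stft(x, fs)
        sigma, flagged = beamform.estimate_noise_covariance(
            fr, np.ones(fr.n_frames, bool)
        )
        assert not flagged
        mid = sigma[64]
        off = mid - np.diag(np.diag(mid))
        assert np.max(np.abs(off)) < 0.3 * np.mean(np.real(np.diag(mid)))

    def test_single_noise_frame_still_invertible(self, rng):
        fs = 16000
        fr = beamform.stft(rng.standard_normal((4, 2048)), fs)
        mask = np.zeros(fr.n_frames, bool)
        mask[0] = True
        sigma, flagged = beamform.estimate_noise_covariance(fr, mask)
        assert flagged
        np.linalg.inv(sigma[10])  # must not raise

    def test_no_noise_frames_directs_to_fallback(self, rng):
        fr = beamform.stft(rng.standard_normal((4, 2048)), 16000)
        with pytest.raises(ValueError, match="edge-interval"):
            beamform.estimate_noise_covariance(fr, np.zeros(fr.n_frames, bool))

    def test_zeroed_frames_give_loaded_zero_matrix(self):
        fr = beamform.stft(np.zeros((4, 2048)), 16000)
        sigma, flagged = beamform.estimate_noise_covariance(
            fr, np.ones(fr.n_frames, bool)
        )
        assert flagged
        assert np.allclose(sigma[5], sigma[5].conj().T)


class TestMVDRWeights:
    def test_identity_covariance_gives_uniform_weights(self, geometry):
        freqs = np.array([1000.0])
        v = beamform.steering_vector(geometry, 30.0, freqs)[0]
        w = beamform.mvdr_weights(v, np.eye(4, dtype=complex))
        np.testing.assert_allclose(w, v / 4.0, atol=1e-12)
        assert np.all(np.abs(np.abs(w) - 0.25) < 1e-12)

    @given(phi=st.floats(-80, 80), seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_distortionless_constraint(self, phi, seed):
        g = ArrayGeometry()
        r = np.random.default_rng(seed)
        freqs = np.linspace(100, 7900, 16)
        v = beamform.steering_vector(g, phi, freqs)
        a = r.standard_normal((16, 4, 4)) + 1j * r.standard_normal((16, 4, 4))
        sigma = a @ np.conj(np.swapaxes(a, 1, 2)) + 0.1 * np.eye(4)
        w = beamform.mvdr_weights(v, sigma)
        c = np.einsum("bl,bl->b", np.conj(w), v)
        np.testing.assert_allclose(c, np.ones(16), atol=1e-9)

    def test_null_steered_at_dominant_interferer(self):
        # 2-mic array, interferer dominating the covariance: the response
        # toward the interferer collapses
        g = ArrayGeometry(mic_offsets=(0.0, 0.08))
        freqs = np.array([1500.0])
        v_look = beamform.steering_vector(g, 0.0, freqs)[0]
        v_int = beamform.steering_vector(g, 45.0, freqs)[0]
        sigma = 100.0 * np.outer(v_int, np.conj(v_int)) + 1e-3 * np.eye(2)
        w = beamform.mvdr_weights(v_look, sigma)
        resp_int = abs(np.vdot(w, v_int))
        assert abs(np.vdot(w, v_look)) == pytest.approx(1.0, abs=1e-9)
        assert resp_int < 0.1

    def test_das_equals_mvdr_for_isotropic_noise(self, geometry):
        # Sigma proportional to I: MVDR reduces to v/L, i.e. D&S up to 1/L
        freqs = np.linspace(100, 7000, 8)
        v = beamform.steering_vector(geometry, -20.0, freqs)
        sigma = np.tile(3.7 * np.eye(4, dtype=complex), (8, 1, 1))
        w = beamform.mvdr_weights(v, sigma)
        np.testing.assert_allclose(w, v / 4.0, atol=1e-12)


class TestMVDRFilter:
    def test_single_channel_passthrough(self, rng):
        x = rng.standard_normal(8000)
        cap = _Cap(x, 16000)
        np.testing.assert_array_equal(beamform.mvdr_filter(cap, 0.0), x)

    def test_noise_free_anechoic_passthrough(self, geometry, rng):
        fs = 16000
        n = fs
        s = np.zeros(n)
        s[int(0.35 * fs): int(0.65 * fs)] = np.sin(
            2 * np.pi * 300 * np.arange(int(0.3 * fs)) / fs
        )
        phi = 20.0
        taus = beamform.das_delays(geometry, phi) * fs
        clean = np.stack([fractional_delay(s, -t) for t in taus])
        clean += 1e-6 * rng.standard_normal(clean.shape)  # non-degenerate edges
        y = beamform.mvdr_filter(_Cap(clean, fs), phi, geometry)
        c = np.corrcoef(y, clean[0])[0, 1]
        assert c > 0.99


class TestSNREstimator:
    def test_constructed_mixture_near_10db(self, rng):
        fs = 16000
        n = 3 * fs
        noise = rng.standard_normal(n) * 0.1
        x = noise.copy()
        interior = slice(int(0.3 * fs), n - int(0.3 * fs))
        m = interior.stop - interior.start
        tone = np.sqrt(10.0) * 0.1 * np.sqrt(2) * np.sin(2 * np.pi * 440 * np.arange(m) / fs)
        x[interior] += tone
        assert beamform.estimate_snr(x, fs) == pytest.approx(10.0, abs=0.5)

    def test_pure_noise_reports_floor(self, rng):
        x = 0.1 * rng.standard_normal(16000)
        assert beamform.estimate_snr(x, 16000) < -20.0

    def test_monotone_in_speech_gain(self, rng):
        fs = 16000
        noise = 1e-3 * rng.standard_normal(2 * fs)
        base = np.zeros(2 * fs)
        base[int(0.5 * fs): int(1.5 * fs)] = np.sin(
            2 * np.pi * 200 * np.arange(fs) / fs
        )
        snrs = [
            beamform.estimate_snr(g * base + noise, fs) for g in (0.5, 1.0, 2.0)
        ]
        assert snrs[0] < snrs[1] < snrs[2]

    def test_too_short_file_rejected(self):
        with pytest.raises(ValueError):
            beamform.estimate_snr(np.zeros(1000), 16000)
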