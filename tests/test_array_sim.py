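"""Scene simulation: RIR geometry and decay, SNR mixing contracts,
dynamic head-motion track, and energy bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyspnea_hri import array_sim
from dyspnea_hri._dsp import das_delays
from dyspnea_hri.config import (
    ConfigurationError,
    MotionProfile,
    RoomSpec,
    SceneConfig,
)


class TestRIR:
    def test_anechoic_is_pure_scaled_delayed_impulse(self, room, geometry):
        rir = array_sim.simulate_rir(room, (2.0, 20.0), geometry, anechoic=True)
        for l in range(geometry.n_mics):
            h = rir.rirs[l]
            assert np.count_nonzero(h) == 1
            assert h[np.argmax(np.abs(h))] > 0

    def test_direct_path_delays_match_steering(self, room, geometry):
        for angle in (0.0, 30.0, -50.0):
            rir = array_sim.simulate_rir(room, (2.0, angle), geometry, anechoic=True)
            peaks = np.array([int(np.argmax(np.abs(rir.rirs[l]))) for l in range(4)])
            lags = peaks - peaks[0]
            expected = -das_delays(geometry, angle) * rir.rate
            assert np.all(np.abs(lags - expected) <= 1.0)

    def test_angle_zero_equal_delays(self, room, geometry):
        rir = array_sim.simulate_rir(room, (1.0, 0.0), geometry, anechoic=True)
        peaks = [int(np.argmax(np.abs(rir.rirs[l]))) for l in range(4)]
        assert len(set(peaks)) == 1

    def test_default_room_rt60_near_half_second(self, room, geometry):
        rir = array_sim.simulate_rir(room, (2.0, 0.0), geometry, seed=0)
        est = array_sim.estimate_rt60(rir.rirs[0], rir.rate)
        assert est.reliable
        assert est.seconds == pytest.approx(0.5, rel=0.15)

    def test_source_outside_room_rejected(self, room, geometry):
        with pytest.raises(ConfigurationError):
            array_sim.simulate_rir(room, (10.0, 0.0), geometry)


class TestGrid:
    def test_default_grid_has_33_conditions(self, room, geometry):
        grid = array_sim.build_rir_grid(room, geometry, t_max=0.06)
        assert len(grid) == 33
        pairs = {(c.distance, c.head_angle) for c in grid}
        assert len(pairs) == 33
        assert pairs == {(d, a) for d in (1.0, 2.0, 3.0) for a in range(-50, 51, 10)}

    def test_single_condition_grid(self, room, geometry):
        grid = array_sim.build_rir_grid(
            room, geometry, distances=[2.0], angles=[0.0], t_max=0.06
        )
        assert len(grid) == 1

    def test_duplicate_conditions_rejected(self, room, geometry):
        with pytest.raises(ConfigurationError):
            array_sim.build_rir_grid(room, geometry, distances=[1.0, 1.0], angles=[0.0])


class TestMixing:
    def test_equal_energy_at_zero_snr_unit_gain(self, rng):
        t = rng.standard_normal(1000)
        n = rng.permutation(t)  # same energy
        out, scaled = array_sim.mix_at_snr(t, n, 0.0, return_components=True)
        np.testing.assert_allclose(scaled, n, atol=1e-12)

    @given(snr=st.floats(-10, 30), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_recomputed_snr_matches_request(self, snr, seed):
        r = np.random.default_rng(seed)
        t = r.standard_normal(2000)
        n = r.standard_normal(2500)
        out, scaled = array_sim.mix_at_snr(t, n, snr, return_components=True)
        got = 10 * np.log10(np.sum(t**2) / np.sum(scaled**2))
        assert got == pytest.approx(snr, abs=1e-9)

    def test_infinite_snr_disables_noise(self, rng):
        t = rng.standard_normal(100)
        out = array_sim.mix_at_snr(t, rng.standard_normal(100), np.inf)
        np.testing.assert_array_equal(out, t)

    def test_zero_energy_noise_rejected(self, rng):
        with pytest.raises(ValueError):
            array_sim.mix_at_snr(rng.standard_normal(100), np.zeros(100), 10.0)

    def test_noise_mixture_ratio_exact(self, rng):
        robot = rng.standard_normal(4000)
        env = rng.standard_normal(4000)
        for ratio in (-5.0, 0.0, 5.0):
            mix = array_sim.make_noise_mixture(robot, env, ratio)
            scaled_env = mix - robot
            got = 10 * np.log10(np.sum(robot**2) / np.sum(scaled_env**2))
            assert got == pytest.approx(ratio, abs=1e-9)

    def test_noise_mixture_env_disabled(self, rng):
        robot = rng.standard_normal(100)
        np.testing.assert_array_equal(array_sim.make_noise_mixture(robot, None, 0.0), robot)

    def test_ratio_draws_centered_on_zero(self, rng):
        # uniform on [-5, 5]: mean of 600 draws within 3 SE of 0
        draws = rng.uniform(-5, 5, 600)
        se = 10 / np.sqrt(12) / np.sqrt(600)
        assert abs(draws.mean()) < 3 * se


class TestNoiseBank:
    def test_all_env_classes_generate_unit_power(self, rng):
        for kind in array_sim.ENV_NOISE_CLASSES:
            x = array_sim.make_env_noise(kind, 8000, 16000, rng)
            assert np.std(x) == pytest.approx(1.0, rel=0.05)

    def test_unknown_class_rejected(self, rng):
        with pytest.raises(ValueError):
            array_sim.make_env_noise("vacuum", 100, 16000, rng)


class TestTrainingCorpus:
    def test_draws_logged_and_within_ranges(self, room, geometry, short_voc):
        grid = array_sim.build_rir_grid(room, geometry, t_max=0.12)
        caps = list(
            array_sim.simulate_training_corpus([short_voc] * 5, grid, room=room, seed=0)
        )
        assert len(caps) == 5
        for cap in caps:
            assert cap.channels.shape == (4, len(short_voc.audio))
            assert 5.0 <= cap.provenance["snr_db"] <= 15.0
            assert -5.0 <= cap.provenance["ratio_db"] <= 5.0
            assert cap.provenance["condition"] in {
                (c.distance, c.head_angle) for c in grid
            }

    def test_energy_bookkeeping_reproduces_logged_snr(self, room, geometry, short_voc):
        grid = array_sim.build_rir_grid(
            room, geometry, distances=[2.0], angles=[0.0], t_max=0.12
        )
        cap = next(
            array_sim.simulate_training_corpus([short_voc], grid, room=room, seed=4)
        )
        got = 10 * np.log10(np.sum(cap.clean_ref**2) / np.sum(cap.noise_ref**2))
        assert got == pytest.approx(cap.provenance["snr_db"], abs=1e-6)


class TestDynamicCapture:
    def test_triangular_track_extrema_and_slope(self):
        motion = MotionProfile(kind="dynamic", rate=0.42, limit=50.0)
        rate = 16000
        n = int(13.0 * rate)
        track = array_sim.triangular_doa_track(n, rate, motion)
        assert track.max() == pytest.approx(50.0, abs=0.5)
        assert track.min() == pytest.approx(-50.0, abs=0.5)
        # slope between turnarounds ~ +/-0.42 rad/s
        mid = np.abs(track) < 40.0
        slopes = np.abs(np.diff(np.deg2rad(track))) * rate
        assert np.median(slopes[mid[:-1]]) == pytest.approx(0.42, rel=0.05)

    def test_full_sweep_within_mean_duration(self):
        # triangular period at 0.42 rad/s over +/-50 deg is ~8.3 s < 12.7 s
        motion = MotionProfile(kind="dynamic")
        period = 4 * np.deg2rad(motion.limit) / motion.rate
        assert period < 12.7
        rate = 1000
        track = array_sim.triangular_doa_track(int(12.7 * rate), rate, motion)
        # both extremes are reached at least once => a full back-and-forth
        assert (track > 49.5).any() and (track < -49.5).any()

    def test_static_degenerate_matches_static_capture(self, room, geometry, short_voc):
        scene = SceneConfig(
            speech_snr_db=np.inf,
            motion=MotionProfile(kind="dynamic", limit=0.0),
            sensor_noise_db=-np.inf,
        )
        cap = array_sim.simulate_dynamic_capture(
            short_voc, room, geometry, scene.motion, scene, seed=0
        )
        assert np.all(cap.doa_track == 0.0)
        # channels equal the uniformly delayed/attenuated source
        ref = cap.clean_ref
        corr = np.corrcoef(cap.channels[0], ref)[0, 1]
        assert corr > 0.999

    def test_bad_block_size_rejected(self, room, geometry, short_voc):
        with pytest.raises(ConfigurationError):
            array_sim.simulate_dynamic_capture(
                short_voc, room, geometry, block_s=0.0
            )


class TestRT60Estimator:
    def test_known_exponential_decay_recovered(self, rng):
        rate = 16000
        rt60 = 0.4
        t = np.arange(int(rate * 0.6)) / rate
        h = rng.standard_normal(len(t)) * 10 ** (-3 * t / rt60)
        est = array_sim.estimate_rt60(h, rate)
        assert est.reliable
        assert est.seconds == pytest.approx(rt60, rel=0.05)

    def test_pure_impulse_flagged(self):
        h = np.zeros(1000)
        h[10] = 1.0
        est = array_sim.estimate_rt60(h, 16000)
        assert not est.reliable

    def test_empty_rir_rejected(self):
        with pytest.raises(ValueError):
            array_sim.estimate_rt60(np.array([]), 16000)


def test_convolution_with_unit_impulse_is_identity(room, geometry, short_voc, rng):
    """Channel built from a one-tap unit RIR reproduces the input."""
    rir = array_sim.RIRCondition(
        0.0, 0.0, np.tile(np.r_[1.0, np.zeros(7)], (4, 1)), short_voc.rate
    )
    cap = array_sim.simulate_static_capture(
        short_voc, room, geometry,
        SceneConfig(speech_snr_db=np.inf, sensor_noise_db=-np.inf),
        seed=0, rir=rir,
    )
    np.testing.assert_allclose(cap.channels[0], short_voc.audio, atol=1e-12)
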