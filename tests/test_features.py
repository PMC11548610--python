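import numpy as np
import pytest

from canegait.errors import DataError, ZeroPowerError
from canegait.features import (
    average_over_cycles, cycle_peak_angular_velocity, cycle_rms,
    extract_trial_features, hamming_periodic, mean_power_frequency,
    power_spectrum,
)
from canegait.io import ImuRecording
from canegait.preprocess import GaitCycle

FS = 120.0
L = 512
BIN = FS / L  # 0.234375 Hz


class TestCycleStatistics:
    def test_rms_alternating(self):
        assert cycle_rms([3, -3, 3, -3]) == pytest.approx(3.0)

    def test_rms_hand_arithmetic(self):
        assert cycle_rms([1, 2, 3, 4]) == pytest.approx(np.sqrt(30 / 4))

    def test_rms_sinusoid_whole_periods(self):
        t = np.arange(240) / FS  # exactly 4 periods of 2 Hz
        x = 1.7 * np.sin(2 * np.pi * 2.0 * t)
        assert cycle_rms(x) == pytest.approx(1.7 / np.sqrt(2), rel=0.01)

    def test_peak_unsigned(self):
        assert cycle_peak_angular_velocity([-5, 2, 4]) == 5.0
        assert cycle_peak_angular_velocity(np.zeros(10)) == 0.0

    def test_average(self):
        assert average_over_cycles([2, 4]) == 3.0
        assert average_over_cycles([7]) == 7.0

    @pytest.mark.parametrize("fn", [cycle_rms, cycle_peak_angular_velocity,
                                    average_over_cycles])
    def test_empty_rejected(self, fn):
        with pytest.raises(DataError):
            fn([])


class TestPowerSpectrum:
    def test_zero_signal_zero_spectrum(self):
        spec = power_spectrum(np.zeros(L), FS)
        assert spec.power.sum() == 0.0
        assert len(spec.power) == L // 2 + 1

    def test_bin_spacing_and_origin(self):
        spec = power_spectrum(np.zeros(L), FS)
        assert spec.frequencies_hz[0] == 0.0
        np.testing.assert_allclose(np.diff(spec.frequencies_hz), BIN)

    def test_wrong_length_rejected(self):
        with pytest.raises(DataError):
            power_spectrum(np.zeros(100), FS)

    def test_on_bin_tone_mainlobe_symmetric(self):
        """Hamming leakage of an on-bin tone is symmetric about its bin."""
        t = np.arange(L) / FS
        x = np.sin(2 * np.pi * 9 * BIN * t)
        p = power_spectrum(x, FS).power
        for j in (1, 2):
            assert p[9 - j] == pytest.approx(p[9 + j], rel=1e-6)

    def test_parseval_energy_identity(self, rng):
        """One-sided power sums to L x time-domain energy of the windowed signal."""
        w = hamming_periodic(L)
        for _ in range(5):
            x = rng.normal(size=L)
            spec = power_spectrum(x, FS)
            np.testing.assert_allclose(spec.power.sum(), L * np.sum((x * w) ** 2),
                                       rtol=1e-9)

    def test_matches_direct_dft_oracle(self, rng):
        """Brute-force O(L^2) DFT agrees with the fast transform."""
        x = rng.normal(size=L)
        w = hamming_periodic(L)
        xw = x * w
        n = np.arange(L)
        k = np.arange(L // 2 + 1)
        direct = np.exp(-2j * np.pi * np.outer(k, n) / L) @ xw
        p_direct = np.abs(direct) ** 2
        p_direct[1:-1] *= 2
        np.testing.assert_allclose(power_spectrum(x, FS).power, p_direct, rtol=1e-9)


class TestMeanPowerFrequency:
    def test_on_bin_tone(self):
        t = np.arange(L) / FS
        x = np.sin(2 * np.pi * 9 * BIN * t)  # 2.109375 Hz
        mpf = mean_power_frequency(power_spectrum(x, FS))
        assert mpf == pytest.approx(9 * BIN, abs=1e-3)

    def test_two_equal_tones_midpoint(self):
        t = np.arange(L) / FS
        x = np.sin(2 * np.pi * 9 * BIN * t) + np.sin(2 * np.pi * 30 * BIN * t + 1.0)
        mpf = mean_power_frequency(power_spectrum(x, FS))
        assert mpf == pytest.approx((9 + 30) / 2 * BIN, abs=5e-3)

    def test_white_noise_flat_spectrum_centroid(self):
        """Mean MPF of white noise approaches the flat-spectrum centroid.

        Included bins are k = 3..42 (0.5 <= f <= 10 Hz), whose centroid
        is (3 + 42)/2 x bin = 5.2734 Hz.
        """
        rng = np.random.default_rng(11)
        mpfs = [mean_power_frequency(power_spectrum(rng.normal(size=L), FS))
                for _ in range(200)]
        assert np.mean(mpfs) == pytest.approx(22.5 * BIN, abs=0.1)

    def test_zero_power_in_band_rejected(self):
        with pytest.raises(ZeroPowerError):
            mean_power_frequency(power_spectrum(np.zeros(L), FS))

    def test_bins_below_band_excluded(self):
        """A large tone below 0.5 Hz must not drag the centroid down.

        The periodic-Hamming mainlobe of an on-bin tone spans one bin
        either side, so a bin-1 tone (0.234 Hz) stays entirely below the
        0.5 Hz edge and only the bin-9 tone counts.
        """
        t = np.arange(L) / FS
        x = 50.0 * np.sin(2 * np.pi * 1 * BIN * t) + np.sin(2 * np.pi * 9 * BIN * t)
        mpf = mean_power_frequency(power_spectrum(x, FS))
        assert mpf == pytest.approx(9 * BIN, abs=1e-3)


def _windowed(acc_fn, gyro_fn):
    t = np.arange(L) / FS
    acc = np.column_stack([acc_fn(t, i) for i in range(3)])
    gyro = np.column_stack([gyro_fn(t, i) for i in range(3)])
    return ImuRecording("t", "s", FS, acc, gyro)


class TestExtractTrialFeatures:
    @pytest.fixture()
    def rec_and_cycles(self):
        rec = _windowed(
            lambda t, i: (i + 1.0) * np.sin(2 * np.pi * 2.0 * t) + 5.0,
            lambda t, i: (i + 1.0) * 10 * np.cos(2 * np.pi * 1.0 * t),
        )
        cycles = [GaitCycle(0, 128, 128 / FS), GaitCycle(128, 256, 128 / FS),
                  GaitCycle(256, 384, 128 / FS), GaitCycle(384, 512, 128 / FS)]
        return rec, cycles

    def test_scale_equivariance(self, rec_and_cycles, config):
        """Doubling acceleration doubles RMS and leaves MPF unchanged."""
        rec, cycles = rec_and_cycles
        f1 = extract_trial_features(rec, cycles, config)
        rec2 = ImuRecording("t", "s", FS, 2.0 * rec.acc, rec.gyro)
        f2 = extract_trial_features(rec2, cycles, config)
        for ax in ("vt", "ap", "ml"):
            assert getattr(f2, f"rms_{ax}") == pytest.approx(
                2 * getattr(f1, f"rms_{ax}"), rel=1e-9)
            assert getattr(f2, f"mpf_{ax}") == pytest.approx(
                getattr(f1, f"mpf_{ax}"), rel=1e-9)

    def test_cycle_order_invariance(self, rec_and_cycles, config):
        rec, cycles = rec_and_cycles
        f1 = extract_trial_features(rec, cycles, config)
        f2 = extract_trial_features(rec, cycles[::-1], config)
        assert f1.as_dict() == pytest.approx(f2.as_dict())

    def test_mean_removal_kills_offset(self, rec_and_cycles, config):
        """The +5 m/s^2 offset must not inflate RMS (gravity handling)."""
        rec, cycles = rec_and_cycles
        f = extract_trial_features(rec, cycles, config)
        assert f.rms_vt == pytest.approx(1.0 / np.sqrt(2), rel=0.01)

    def test_mpf_inside_band(self, rec_and_cycles, config):
        rec, cycles = rec_and_cycles
        f = extract_trial_features(rec, cycles, config)
        lo, hi = config.mpf_band_hz
        for ax in ("vt", "ap", "ml"):
            assert lo <= getattr(f, f"mpf_{ax}") <= hi

    def test_noiseless_trial_matches_generator_closed_forms(
            self, clean_single_harmonic_trial):
        """End-to-end features recover the generating parameters within 2%."""
        trial = clean_single_harmonic_trial
        p = trial.params
        f = trial.true_features
        f_stride = 1.0 / p.stride_time_mean_s
        assert f.rms_vt == pytest.approx(p.a_vt / np.sqrt(2), rel=0.02)
        assert f.mpf_vt == pytest.approx(f_stride, abs=BIN)
        assert f.pav_ap == pytest.approx(p.g_ap, rel=0.02)
        assert f.stride_time_s == pytest.approx(p.stride_time_mean_s, abs=1 / FS)
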