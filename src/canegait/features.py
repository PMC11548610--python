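"""Trial-level gait features from the windowed cane-IMU signal.

Ten features per trial, in VT/AP/ML axis order:

* RMS of the filtered acceleration, computed per gait cycle and
  averaged over cycles (m/s²);
* mean power frequency (MPF) of the acceleration — the power-weighted
  mean frequency (spectral centroid) of a 512-point FFT taken through a
  periodic Hamming window, restricted to the 0.5–10 Hz band (Hz);
* peak angular velocity per gait cycle, averaged over cycles (deg/s);
* stride time, the mean cane-contact-to-contact interval (s).

The per-axis window mean is removed before both the RMS and the FFT:
the VT channel otherwise carries the ~9.8 m/s² gravity component,
which would dominate the RMS and leak into the low bins. This is
toggleable via ``RunConfig.remove_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ZeroPowerError
from .io import AXES, ImuRecording, RunConfig, default_config
from .preprocess import GaitCycle


def cycle_rms(segment: np.ndarray) -> float:
    """Root mean square of one cycle's (mean-removed) signal segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise DataError("cannot take RMS of an empty segment")
    return float(np.sqrt(np.mean(segment**2)))


def cycle_peak_angular_velocity(segment: np.ndarray) -> float:
    """Peak unsigned angular velocity over one cycle, max |ω|."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise DataError("cannot take peak of an empty segment")
    return float(np.max(np.abs(segment)))


def average_over_cycles(values) -> float:
    """Arithmetic mean of per-cycle values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DataError("no per-cycle values to average")
    return float(values.mean())


@dataclass
class PowerSpectrum:
    """One-sided power spectrum; bin spacing sample_rate / window_len."""

    frequencies_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.frequencies_hz.shape != self.power.shape:
            raise DataError("frequency and power arrays must have equal length")


def hamming_periodic(length: int) -> np.ndarray:
    """Periodic Hamming window w[n] = 0.54 - 0.46 cos(2πn/L)."""
    n = np.arange(length)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / length)


def power_spectrum(x: np.ndarray, sample_rate_hz: float, window_len: int = 512) -> PowerSpectrum:
    """Windowed one-sided power spectrum of one axis signal.

    The input must be exactly ``window_len`` samples (already
    mean-removed). Power is |DFT|² of the Hamming-windowed signal with
    interior bins doubled to fold the negative frequencies in.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != window_len:
        raise DataError(f"power_spectrum expects exactly {window_len} samples, got {x.shape}")
    w = hamming_periodic(window_len)
    spec = np.fft.rfft(x * w)
    power = np.abs(spec) ** 2
    power[1:-1] *= 2.0  # fold negative-frequency halves; DC and Nyquist are unique
    freqs = np.fft.rfftfreq(window_len, d=1.0 / sample_rate_hz)
    return PowerSpectrum(frequencies_hz=freqs, power=power)


def mean_power_frequency(spec: PowerSpectrum, band_hz: tuple[float, float] = (0.5, 10.0)) -> float:
    """Power-weighted mean frequency over the band (endpoints inclusive)."""
    lo, hi = band_hz
    if not lo < hi:
        raise DataError(f"band must be (low, high) with low < high, got {band_hz}")
    f = spec.frequencies_hz
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        raise ZeroPowerError(f"no spectral bins inside band {band_hz}")
    p = spec.power[mask]
    total = p.sum()
    if not total > 0:
        raise ZeroPowerError(f"zero spectral power inside band {band_hz}")
    return float(np.sum(f[mask] * p) / total)


@dataclass
class TrialFeatures:
    """The 10-value feature vector for one trial."""

    rms_vt: float
    rms_ap: float
    rms_ml: float
    mpf_vt: float
    mpf_ap: float
    mpf_ml: float
    pav_vt: float
    pav_ap: float
    pav_ml: float
    stride_time_s: float
    n_cycles: int = 0

    def as_dict(self) -> dict:
        return {
            "rms_vt": self.rms_vt, "rms_ap": self.rms_ap, "rms_ml": self.rms_ml,
            "mpf_vt": self.mpf_vt, "mpf_ap": self.mpf_ap, "mpf_ml": self.mpf_ml,
            "pav_vt": self.pav_vt, "pav_ap": self.pav_ap, "pav_ml": self.pav_ml,
            "stride_time_s": self.stride_time_s,
        }


def extract_trial_features(
    windowed: ImuRecording,
    cycles: list[GaitCycle],
    config: RunConfig | None = None,
) -> TrialFeatures:
    """Compute the 10 features from a windowed recording and its cycles.

    RMS and peak angular velocity are computed per cycle then averaged;
    MPF is computed once per axis on the full analysis window.
    """
    cfg = config or default_config()
    if len(cycles) < 1:
        raise DataError("need at least one complete gait cycle")
    acc = windowed.acc.astype(float)
    if cfg.remove_mean:
        acc = acc - acc.mean(axis=0, keepdims=True)
    gyro = windowed.gyro

    values: dict[str, float] = {}
    for i, axis in enumerate(AXES):
        values[f"rms_{axis}"] = average_over_cycles(
            [cycle_rms(acc[c.start : c.end, i]) for c in cycles]
        )
        values[f"pav_{axis}"] = average_over_cycles(
            [cycle_peak_angular_velocity(gyro[c.start : c.end, i]) for c in cycles]
        )
        spec = power_spectrum(acc[:, i], windowed.sample_rate_hz, cfg.window_len_samples)
        values[f"mpf_{axis}"] = mean_power_frequency(spec, cfg.mpf_band_hz)

    stride_time = average_over_cycles([c.duration_s for c in cycles])
    return TrialFeatures(
        rms_vt=values["rms_vt"], rms_ap=values["rms_ap"], rms_ml=values["rms_ml"],
        mpf_vt=values["mpf_vt"], mpf_ap=values["mpf_ap"], mpf_ml=values["mpf_ml"],
        pav_vt=values["pav_vt"], pav_ap=values["pav_ap"], pav_ml=values["pav_ml"],
        stride_time_s=stride_time,
        n_cycles=len(cycles),
    )
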