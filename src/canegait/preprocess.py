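"""Signal conditioning and cane ground-contact detection.

The processing chain mirrors the measurement protocol: each channel is
low-pass filtered with a fourth-order Butterworth at 10 Hz, cane–ground
impacts are located as spikes in the jerk norm (Euclidean norm of the
time derivative of the filtered 3-axis acceleration), a fixed 512-sample
analysis window is cut from the first contact, and gait cycles are the
intervals between successive cane contacts.

Filtering is applied forward–backward (zero phase) so that detected
event times are not shifted relative to the raw signal; the effective
amplitude response is therefore the squared single-pass Butterworth
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError, NoContactError, ShortTrialError, TooFewCyclesError
from .io import ContactConfig, FilterConfig, ImuRecording, RunConfig


@dataclass
class FilteredRecording:
    """An :class:`ImuRecording` after zero-phase low-pass filtering."""

    recording: ImuRecording
    cutoff_hz: float
    order: int
    phase_mode: str = "zero-phase"

    @property
    def acc(self) -> np.ndarray:
        return self.recording.acc

    @property
    def gyro(self) -> np.ndarray:
        return self.recording.gyro

    @property
    def sample_rate_hz(self) -> float:
        return self.recording.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return self.recording.n_samples


def lowpass_filter(
    x: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = 10.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a 1-D sequence.

    Forward–backward application (``sosfiltfilt``): no phase shift, unit
    DC gain, output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DataError("lowpass_filter expects a 1-D sequence")
    if not 0 < cutoff_hz < sample_rate_hz / 2:
        raise DataError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={sample_rate_hz / 2} Hz)"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sample_rate_hz, output="sos")
    # sosfiltfilt needs padlen < len(x); 3*order is also the documented minimum
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= max(3 * order, padlen):
        raise DataError(f"input too short to filter: {len(x)} samples")
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def filter_recording(rec: ImuRecording, config: RunConfig | FilterConfig | None = None) -> FilteredRecording:
    """Filter all six channels of a recording."""
    fc = config.filter if isinstance(config, RunConfig) else (config or FilterConfig())
    acc = np.column_stack(
        [lowpass_filter(rec.acc[:, i], rec.sample_rate_hz, fc.cutoff_hz, fc.order) for i in range(3)]
    )
    gyro = np.column_stack(
        [lowpass_filter(rec.gyro[:, i], rec.sample_rate_hz, fc.cutoff_hz, fc.order) for i in range(3)]
    )
    filtered = ImuRecording(
        trial_id=rec.trial_id,
        subject_id=rec.subject_id,
        sample_rate_hz=rec.sample_rate_hz,
        acc=acc,
        gyro=gyro,
    )
    return FilteredRecording(filtered, cutoff_hz=fc.cutoff_hz, order=fc.order)


def jerk_norm(acc: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """Euclidean norm of the per-axis first-difference jerk, in m/s³.

    A backward first difference (not centered) keeps impact spikes
    sharp. The first value is duplicated so the output has the input
    length; ``out[i]`` is the jerk magnitude between samples i-1 and i.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise DataError("jerk_norm expects an (N, 3) acceleration array")
    if len(acc) < 2:
        raise DataError("jerk_norm needs at least 2 samples")
    d = np.diff(acc, axis=0) * sample_rate_hz
    j = np.linalg.norm(d, axis=1)
    return np.concatenate([[j[0]], j])


def detect_cane_contacts(
    jerk: np.ndarray,
    sample_rate_hz: float,
    threshold_k: float = 3.0,
    min_separation_s: float = 0.5,
) -> np.ndarray:
    """Detect cane ground contacts as prominent jerk-norm spikes.

    Local maxima exceeding ``mean + threshold_k * sd`` of the series are
    accepted greedily in descending height, enforcing a refractory
    period of ``min_separation_s`` (stride times are ~1 s, so 0.5 s
    separates consecutive contacts safely), then re-sorted by time.
    """
    jerk = np.asarray(jerk, dtype=float)
    if jerk.size == 0:
        raise DataError("empty jerk series")
    threshold = jerk.mean() + threshold_k * jerk.std()
    peaks, props = sps.find_peaks(jerk, height=threshold)
    if peaks.size == 0:
        raise NoContactError("no jerk-norm spike exceeds the contact threshold")
    min_gap = int(round(min_separation_s * sample_rate_hz))
    order = np.argsort(props["peak_heights"])[::-1]
    accepted: list[int] = []
    for idx in peaks[order]:
        if all(abs(int(idx) - a) >= min_gap for a in accepted):
            accepted.append(int(idx))
    return np.array(sorted(accepted), dtype=int)


def extract_analysis_window(
    rec: FilteredRecording | ImuRecording,
    contacts: np.ndarray,
    window_len: int = 512,
) -> tuple[ImuRecording, np.ndarray]:
    """Cut ``window_len`` samples starting at the first cane contact.

    Returns the windowed recording and the contacts that fall inside the
    window, re-indexed relative to its start. Trials too short to hold
    the window are excluded via :class:`ShortTrialError`, mirroring the
    study's exclusion of unmeasurable trials.
    """
    base = rec.recording if isinstance(rec, FilteredRecording) else rec
    contacts = np.asarray(contacts, dtype=int)
    if contacts.size == 0:
        raise NoContactError("no contacts supplied")
    c0 = int(contacts[0])
    if c0 + window_len > base.n_samples:
        raise ShortTrialError(
            f"trial {base.trial_id!r}: first contact at sample {c0} + window "
            f"{window_len} exceeds recording length {base.n_samples}"
        )
    windowed = ImuRecording(
        trial_id=base.trial_id,
        subject_id=base.subject_id,
        sample_rate_hz=base.sample_rate_hz,
        acc=base.acc[c0 : c0 + window_len].copy(),
        gyro=base.gyro[c0 : c0 + window_len].copy(),
    )
    rel = contacts - c0
    inside = rel[(rel >= 0) & (rel < window_len)]
    return windowed, inside


@dataclass(frozen=True)
class GaitCycle:
    """Half-open interval [start, end) between successive cane contacts."""

    start: int
    end: int
    duration_s: float


def segment_cycles(contacts_in_window: np.ndarray, sample_rate_hz: float) -> list[GaitCycle]:
    """Gait cycles between consecutive cane contacts inside the window."""
    contacts = np.asarray(contacts_in_window, dtype=int)
    if contacts.size < 2:
        raise TooFewCyclesError(
            f"need >= 2 contacts in the window to form a cycle, got {contacts.size}"
        )
    if not (np.diff(contacts) > 0).all():
        raise DataError("contacts must be strictly increasing")
    return [
        GaitCycle(int(a), int(b), (int(b) - int(a)) / sample_rate_hz)
        for a, b in zip(contacts[:-1], contacts[1:])
    ]
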