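"""Synthetic two-point cane gait: signal generator and cohort builder.

The generator emulates the signal class the analysis assumes rather
than cane–body dynamics: each acceleration axis is a quasi-periodic
sum of up to four stride harmonics (axis amplitude × harmonic
weights), with a sharp exponentially decaying impact transient added
at every cane ground contact and white Gaussian sensor noise on top;
the VT channel additionally carries the gravity offset. Angular
velocity is a raised-cosine swing bump per stride scaled to the
per-axis peak. Stride periods are i.i.d. normal (truncated at ±3 sd),
so contact times carry realistic stride-time variability.

Cohorts pair a "frail" and a "robust" parameter preset (loaded from
``data/presets.yaml``). Subject-level log-normal random effects
correlate the trials of one subject; frailty labels follow the
intended preset, while 5-item exercise-questionnaire responses are
drawn with group-dependent negative-answer probabilities so that the
"three or more negative answers" rule reproduces the intended label
for nearly all subjects.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .features import TrialFeatures, extract_trial_features
from .io import ImuRecording, RunConfig, default_config
from .preprocess import extract_analysis_window, filter_recording, segment_cycles

#: Fraction of the impact amplitude coupled into each acceleration axis.
IMPACT_COUPLING = {"vt": 1.0, "ap": 0.35, "ml": 0.20}

#: Fixed harmonic phase offsets (rad); arbitrary but deterministic.
HARMONIC_PHASES = (0.0, np.pi / 3, 2 * np.pi / 3, np.pi)

GRAVITY_MS2 = 9.80665


@dataclass
class GaitSimParams:
    """Parameters of one simulated walking trial."""

    stride_time_mean_s: float = 1.10
    stride_time_sd_s: float = 0.05
    a_vt: float = 2.2              # oscillation amplitude, m/s²
    a_ap: float = 1.8
    a_ml: float = 1.0
    weights_vt: tuple = (0.55, 0.25, 0.12, 0.08)   # harmonic weights, sum 1
    weights_ap: tuple = (0.60, 0.22, 0.11, 0.07)
    weights_ml: tuple = (0.65, 0.20, 0.10, 0.05)
    impact_amp: float = 12.0       # cane-strike transient peak, m/s²
    impact_tau_s: float = 0.05     # transient decay time constant
    g_vt: float = 30.0             # peak swing angular velocity, deg/s
    g_ap: float = 100.0
    g_ml: float = 40.0
    noise_acc: float = 0.15        # sensor noise sd, m/s²
    noise_gyro: float = 1.5        # sensor noise sd, deg/s
    n_strides: int = 8
    sample_rate_hz: float = 120.0
    lead_in_s: float = 0.6         # signal before the first cane contact
    tail_s: float = 0.5
    include_gravity: bool = True

    def validate(self) -> "GaitSimParams":
        amps = (self.a_vt, self.a_ap, self.a_ml, self.impact_amp,
                self.g_vt, self.g_ap, self.g_ml, self.noise_acc, self.noise_gyro)
        if any(a < 0 for a in amps):
            raise ConfigError("all amplitudes must be >= 0")
        if not self.stride_time_mean_s > 0:
            raise ConfigError("stride_time_mean_s must be positive")
        if self.stride_time_sd_s < 0:
            raise ConfigError("stride_time_sd_s must be >= 0")
        if self.n_strides < 3:
            raise ConfigError("n_strides must be >= 3")
        for name in ("weights_vt", "weights_ap", "weights_ml"):
            w = np.asarray(getattr(self, name), dtype=float)
            if len(w) != 4 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
                raise ConfigError(f"{name} must be 4 non-negative weights summing to 1")
        return self

    def scaled(self, acc_mult: float = 1.0, gyro_mult: float = 1.0,
               stride_mult: float = 1.0) -> "GaitSimParams":
        """A copy with amplitude/stride multipliers applied (random effects)."""
        p = copy.deepcopy(self)
        p.a_vt *= acc_mult
        p.a_ap *= acc_mult
        p.a_ml *= acc_mult
        p.impact_amp *= acc_mult
        p.g_vt *= gyro_mult
        p.g_ap *= gyro_mult
        p.g_ml *= gyro_mult
        p.stride_time_mean_s *= stride_mult
        return p


@dataclass
class SimulatedTrial:
    recording: ImuRecording
    true_contacts: np.ndarray            # sample indices, length n_strides + 1
    true_stride_times_s: np.ndarray
    true_features: TrialFeatures | None  # reference pipeline on the noiseless signal
    params: GaitSimParams


@dataclass(frozen=True)
class KclResponses:
    """Negative-answer indicators for the five exercise questionnaire items."""

    items: tuple

    def __post_init__(self) -> None:
        if len(self.items) != 5 or any(i not in (0, 1) for i in self.items):
            raise DataError("KclResponses needs exactly five binary items")

    @property
    def n_negative(self) -> int:
        return int(sum(self.items))


def kcl_label(responses: KclResponses) -> str:
    """Frailty rule: frail iff three or more negative answers."""
    return "frail" if responses.n_negative >= 3 else "robust"


def _rng_from(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _truncated_normal(rng, mean, sd, size):
    """Normal draws truncated at ±3 sd (rejection sampling)."""
    if sd == 0:
        return np.full(size, mean, dtype=float)
    out = rng.normal(mean, sd, size)
    bad = np.abs(out - mean) > 3 * sd
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = np.abs(out - mean) > 3 * sd
    return out


def _stride_phase(t: np.ndarray, contact_times: np.ndarray) -> np.ndarray:
    """Phase in stride units: hits integer k exactly at contact k.

    Linear between contacts, extrapolated at the edge stride rates
    outside the walking interval.
    """
    phase = np.interp(t, contact_times, np.arange(len(contact_times), dtype=float))
    first, last = contact_times[0], contact_times[-1]
    rate0 = 1.0 / (contact_times[1] - contact_times[0])
    rate1 = 1.0 / (contact_times[-1] - contact_times[-2])
    before = t < first
    after = t > last
    phase[before] = (t[before] - first) * rate0
    phase[after] = (len(contact_times) - 1) + (t[after] - last) * rate1
    return phase


def simulate_trial(
    params: GaitSimParams,
    seed,
    trial_id: str = "trial",
    subject_id: str = "subject",
    compute_true_features: bool = True,
    config: RunConfig | None = None,
) -> SimulatedTrial:
    """Generate one trial; identical seed gives bit-identical output.

    ``true_features`` is the reference pipeline (filter → window at the
    first true contact → cycles between true contacts → features)
    applied to the noiseless version of the same signal.
    """
    params.validate()
    rng = _rng_from(seed)
    fs = params.sample_rate_hz

    strides = _truncated_normal(rng, params.stride_time_mean_s, params.stride_time_sd_s,
                                params.n_strides)
    contact_times = params.lead_in_s + np.concatenate([[0.0], np.cumsum(strides)])
    duration = contact_times[-1] + params.tail_s
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    true_contacts = np.round(contact_times * fs).astype(int)
    # place impacts exactly on sample instants so ground truth is exact
    contact_times_snapped = true_contacts / fs
    phase = _stride_phase(t, contact_times_snapped)

    acc_clean = np.zeros((n, 3))
    weights = (params.weights_vt, params.weights_ap, params.weights_ml)
    amps = (params.a_vt, params.a_ap, params.a_ml)
    for ax in range(3):
        sig = np.zeros(n)
        for k, (w, ph) in enumerate(zip(weights[ax], HARMONIC_PHASES), start=1):
            sig += w * amps[ax] * np.sin(2 * np.pi * k * phase + ph)
        acc_clean[:, ax] = sig
    # impact transient at each cane contact, coupled into all three axes
    if params.impact_amp > 0:
        tau = params.impact_tau_s
        span = int(round(6 * tau * fs)) + 1
        for tc, ci in zip(contact_times_snapped, true_contacts):
            sl = slice(ci, min(ci + span, n))
            pulse = np.exp(-(t[sl] - tc) / tau)
            for ax, axis in enumerate(("vt", "ap", "ml")):
                acc_clean[sl, ax] += IMPACT_COUPLING[axis] * params.impact_amp * pulse

    frac = np.mod(phase, 1.0)
    in_walk = (phase >= 0) & (phase <= params.n_strides)
    bump = 0.5 * (1.0 - np.cos(2 * np.pi * frac)) * in_walk
    gyro_clean = np.column_stack([params.g_vt * bump, params.g_ap * bump, params.g_ml * bump])

    if params.include_gravity:
        acc_clean[:, 0] += GRAVITY_MS2

    acc = acc_clean + rng.normal(0.0, params.noise_acc, (n, 3))
    gyro = gyro_clean + rng.normal(0.0, params.noise_gyro, (n, 3))

    rec = ImuRecording(trial_id=trial_id, subject_id=subject_id,
                       sample_rate_hz=fs, acc=acc, gyro=gyro)

    true_features = None
    if compute_true_features:
        clean = ImuRecording(trial_id=trial_id, subject_id=subject_id,
                             sample_rate_hz=fs, acc=acc_clean, gyro=gyro_clean)
        cfg = config or default_config()
        filtered = filter_recording(clean, cfg)
        windowed, inside = extract_analysis_window(filtered, true_contacts,
                                                   cfg.window_len_samples)
        cycles = segment_cycles(inside, fs)
        true_features = extract_trial_features(windowed, cycles, cfg)

    return SimulatedTrial(
        recording=rec,
        true_contacts=true_contacts,
        true_stride_times_s=strides,
        true_features=true_features,
        params=params,
    )


# ---------------------------------------------------------------------------
# group presets and cohorts


@dataclass
class GroupProfile:
    """Named parameter presets plus cohort-level variation settings."""

    presets: dict                    # {"robust": GaitSimParams, "frail": GaitSimParams}
    kcl_p_negative: dict = field(default_factory=lambda: {"robust": 0.15, "frail": 0.85})
    subject_amp_sd: float = 0.1      # log-normal sd of per-subject amplitude multiplier
    subject_gyro_sd: float = 0.1
    subject_stride_sd: float = 0.03
    trial_amp_sd: float = 0.05       # within-subject trial-to-trial jitter

    def validate(self) -> "GroupProfile":
        for name in ("robust", "frail"):
            if name not in self.presets:
                raise ConfigError(f"profile missing preset {name!r}")
            self.presets[name].validate()
        return self


def _presets_doc() -> dict:
    text = (importlib.resources.files("canegait") / "data" / "presets.yaml").read_text()
    return yaml.safe_load(text)


def load_profile(name: str = "default") -> GroupProfile:
    """Load a calibrated group profile from the packaged presets file.

    Available: ``default`` (frail/robust differ per the observed group
    pattern), ``zero_signal`` (identical groups), ``well_separated``
    (exaggerated group differences for classifier sanity checks).
    """
    doc = _presets_doc()
    if name not in doc["profiles"]:
        raise ConfigError(f"unknown profile {name!r}; available: {sorted(doc['profiles'])}")
    prof = doc["profiles"][name]
    presets = {}
    for group in ("robust", "frail"):
        d = dict(doc["base_params"])
        d.update(prof.get(group, {}))
        for key in ("weights_vt", "weights_ap", "weights_ml"):
            d[key] = tuple(d[key])
        presets[group] = GaitSimParams(**d).validate()
    kwargs = {k: v for k, v in prof.items() if k not in ("robust", "frail")}
    return GroupProfile(presets=presets, **kwargs).validate()


def default_trial_allocation(n_subjects: int, n_trials: int) -> list[int]:
    """Spread n_trials over n_subjects, sizes differing by at most one."""
    base, extra = divmod(n_trials, n_subjects)
    return [base + 1 if i < extra else base for i in range(n_subjects)]


def simulate_cohort(
    profile: GroupProfile | None = None,
    n_frail_subjects: int = 14,
    n_robust_subjects: int = 31,
    trials_per_subject: int | Sequence[int] | None = None,
    seed: int = 0,
    compute_true_features: bool = False,
    config: RunConfig | None = None,
):
    """Simulate a two-group cohort of cane-gait trials.

    Defaults mirror the study composition: 14 frail and 31 robust
    subjects contributing 37 and 94 trials (2–4 trials each). Returns
    ``(manifest, trials, kcl)`` where manifest is a DataFrame with
    columns subject_id, trial_id, trial_file, frail_label, kcl_label;
    trials is a list of :class:`SimulatedTrial`; kcl maps subject_id to
    :class:`KclResponses`.
    """
    import pandas as pd

    profile = (profile or load_profile("default")).validate()
    if n_frail_subjects < 0 or n_robust_subjects < 0 or n_frail_subjects + n_robust_subjects < 1:
        raise ConfigError("need at least one subject")

    groups = [("frail", n_frail_subjects), ("robust", n_robust_subjects)]
    # study trial density: 37 trials / 14 frail, 94 / 31 robust
    density = {"frail": 37 / 14, "robust": 94 / 31}

    root = np.random.SeedSequence(seed)
    rows = []
    trials: list[SimulatedTrial] = []
    kcl: dict[str, KclResponses] = {}
    subj_counter = 0
    for group, n_subj in groups:
        if n_subj == 0:
            continue
        if trials_per_subject is None:
            alloc = default_trial_allocation(n_subj, int(round(n_subj * density[group])))
        elif isinstance(trials_per_subject, int):
            alloc = [trials_per_subject] * n_subj
        else:
            alloc = list(trials_per_subject)[:n_subj]
            if len(alloc) != n_subj:
                raise ConfigError("per-subject trial list shorter than subject count")
        preset = profile.presets[group]
        for j in range(n_subj):
            subj_counter += 1
            sid = f"S{subj_counter:03d}"
            subj_ss = root.spawn(1)[0]
            subj_rng = np.random.default_rng(subj_ss)
            amp_mult = float(np.exp(subj_rng.normal(0.0, profile.subject_amp_sd)))
            gyro_mult = float(np.exp(subj_rng.normal(0.0, profile.subject_gyro_sd)))
            stride_mult = float(np.exp(subj_rng.normal(0.0, profile.subject_stride_sd)))
            p_neg = profile.kcl_p_negative[group]
            kcl[sid] = KclResponses(tuple(int(b) for b in subj_rng.random(5) < p_neg))
            for k in range(alloc[j]):
                tid = f"{sid}_T{k + 1}"
                trial_amp = float(np.exp(subj_rng.normal(0.0, profile.trial_amp_sd)))
                params = preset.scaled(acc_mult=amp_mult * trial_amp,
                                       gyro_mult=gyro_mult * trial_amp,
                                       stride_mult=stride_mult)
                trial = simulate_trial(
                    params, subj_ss.spawn(1)[0], trial_id=tid, subject_id=sid,
                    compute_true_features=compute_true_features, config=config,
                )
                trials.append(trial)
                rows.append({
                    "subject_id": sid,
                    "trial_id": tid,
                    "trial_file": f"{tid}.csv",
                    "frail_label": group,
                    "kcl_label": kcl_label(kcl[sid]),
                })
    manifest = pd.DataFrame(rows)
    return manifest, trials, kcl
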