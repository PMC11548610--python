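"""On-disk formats and run configuration.

A walking trial is a comma-separated, dot-decimal, UTF-8 CSV with one
header row and the seven columns ``time_s, acc_vt, acc_ap, acc_ml,
gyr_vt, gyr_ap, gyr_ml``: tri-axial acceleration in m/s² and angular
velocity in deg/s, expressed along the vertical (VT), anteroposterior
(AP) and mediolateral (ML) anatomical axes, sampled at a fixed rate
(120 Hz in the study protocol). Channels are taken as already aligned
with the anatomical frame and in those units; the reader performs no
unit conversion or orientation correction. Lines starting with ``#``
are provenance comments and are skipped.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, FormatError, RateMismatchError

TRIAL_COLUMNS = ("time_s", "acc_vt", "acc_ap", "acc_ml", "gyr_vt", "gyr_ap", "gyr_ml")
AXES = ("vt", "ap", "ml")

#: Column order of the 10 trial-level gait features.
FEATURE_COLUMNS = (
    "rms_vt", "rms_ap", "rms_ml",
    "mpf_vt", "mpf_ap", "mpf_ml",
    "pav_vt", "pav_ap", "pav_ml",
    "stride_time_s",
)
ID_COLUMNS = ("trial_id", "subject_id", "frail_label")


@dataclass
class ImuRecording:
    """One walking trial from the cane-mounted IMU.

    ``acc`` and ``gyro`` are (N, 3) arrays in VT/AP/ML order, units
    m/s² and deg/s.
    """

    trial_id: str
    subject_id: str
    sample_rate_hz: float
    acc: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise DataError(f"acc must be (N, 3), got {self.acc.shape}")
        if self.gyro.shape != self.acc.shape:
            raise DataError(
                f"gyro shape {self.gyro.shape} differs from acc shape {self.acc.shape}"
            )
        if len(self.acc) < 2:
            raise DataError("recording needs at least 2 samples")
        if not self.sample_rate_hz > 0:
            raise DataError("sample_rate_hz must be positive")
        if not (np.isfinite(self.acc).all() and np.isfinite(self.gyro).all()):
            raise DataError("recording contains NaN or infinite samples")

    @property
    def n_samples(self) -> int:
        return len(self.acc)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


def read_trial_csv(
    path: str | Path,
    declared_rate_hz: float = 120.0,
    trial_id: str | None = None,
    subject_id: str = "",
) -> ImuRecording:
    """Read and validate one trial CSV.

    The sample rate is inferred from the median time step and must agree
    with ``declared_rate_hz`` within 1 %; the declared rate is stored.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trial file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        raise FormatError(f"{path}: unexpected columns {extra}")
    if len(df) < 2:
        raise DataError(f"{path}: fewer than 2 samples")
    if df[list(TRIAL_COLUMNS)].isna().any().any():
        raise DataError(f"{path}: missing values present")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if not (dt > 0).all():
        raise DataError(f"{path}: time column is not strictly increasing")
    inferred = 1.0 / float(np.median(dt))
    if abs(inferred - declared_rate_hz) > 0.01 * declared_rate_hz:
        raise RateMismatchError(
            f"{path}: inferred rate {inferred:.3f} Hz differs from declared "
            f"{declared_rate_hz:.3f} Hz by more than 1%"
        )
    return ImuRecording(
        trial_id=trial_id if trial_id is not None else path.stem,
        subject_id=subject_id,
        sample_rate_hz=declared_rate_hz,
        acc=df[["acc_vt", "acc_ap", "acc_ml"]].to_numpy(dtype=float),
        gyro=df[["gyr_vt", "gyr_ap", "gyr_ml"]].to_numpy(dtype=float),
    )


def write_trial_csv(rec: ImuRecording, path: str | Path, header_comment: str | None = None) -> Path:
    """Write a trial in the documented CSV dialect (12 significant digits)."""
    path = Path(path)
    t = rec.time()
    df = pd.DataFrame(
        {
            "time_s": t,
            "acc_vt": rec.acc[:, 0],
            "acc_ap": rec.acc[:, 1],
            "acc_ml": rec.acc[:, 2],
            "gyr_vt": rec.gyro[:, 0],
            "gyr_ap": rec.gyro[:, 1],
            "gyr_ml": rec.gyro[:, 2],
        }
    )
    buf = _stdio.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    df.to_csv(buf, index=False, float_format="%.12g")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# cohort manifest

MANIFEST_COLUMNS = ("subject_id", "trial_id", "trial_file", "frail_label")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the cohort manifest; validates labels, uniqueness, non-null."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: manifest missing column {col!r}")
    if df["trial_file"].duplicated().any():
        raise DataError(f"{path}: duplicate trial_file entries")
    if df["frail_label"].isna().any():
        raise DataError(f"{path}: null frail_label")
    bad = set(df["frail_label"]) - {"frail", "robust"}
    if bad:
        raise DataError(f"{path}: unknown frail_label values {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> Path:
    path = Path(path)
    buf = _stdio.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# feature table


def write_feature_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> Path:
    """Write the per-trial feature table.

    One row per trial: ``trial_id, subject_id, frail_label`` then the 10
    features in :data:`FEATURE_COLUMNS` order. Values round-trip through
    :func:`read_feature_table` to 12 significant digits.
    """
    for col in ID_COLUMNS + FEATURE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"feature table missing column {col!r}")
    if len(df) == 0:
        raise DataError("feature table is empty")
    if df["trial_id"].duplicated().any():
        dups = df.loc[df["trial_id"].duplicated(), "trial_id"].tolist()
        raise DataError(f"duplicate trial_id values: {dups}")
    path = Path(path)
    out = df[list(ID_COLUMNS + FEATURE_COLUMNS)]
    buf = _stdio.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    out.to_csv(buf, index=False, float_format="%.12g")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ID_COLUMNS + FEATURE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: feature table missing column {col!r}")
    if df[list(FEATURE_COLUMNS)].isna().any().any():
        raise DataError(f"{path}: feature table contains missing values")
    return df


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class FilterConfig:
    cutoff_hz: float = 10.0   # low-pass cutoff
    order: int = 4            # Butterworth order (single pass)


@dataclass
class ContactConfig:
    threshold_k: float = 3.0        # peaks above mean + k·sd of the jerk norm
    min_separation_s: float = 0.5   # refractory period between contacts


@dataclass
class CvConfig:
    n_folds: int = 10
    seed: int = 0
    mode: str = "trial-random"      # or "subject-grouped"
    search_budget: int = 1          # randomized hyperparameter draws (1 = defaults)


@dataclass
class RunConfig:
    """Full analysis configuration with study-protocol defaults."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    contacts: ContactConfig = field(default_factory=ContactConfig)
    window_len_samples: int = 512
    mpf_band_hz: tuple[float, float] = (0.5, 10.0)
    remove_mean: bool = True        # subtract per-axis window mean before RMS/FFT
    positive_label: str = "frail"
    cv: CvConfig = field(default_factory=CvConfig)
    models: dict = field(default_factory=dict)   # per-model hyperparameter overrides

    def validate(self) -> "RunConfig":
        w = self.window_len_samples
        if w < 2 or (w & (w - 1)) != 0:
            raise ConfigError(f"window_len_samples must be a power of two, got {w}")
        lo, hi = self.mpf_band_hz
        if not lo < hi:
            raise ConfigError(f"mpf_band_hz must be (low, high) with low < high, got {self.mpf_band_hz}")
        if self.cv.n_folds < 2:
            raise ConfigError("cv.n_folds must be >= 2")
        if self.cv.mode not in ("trial-random", "subject-grouped"):
            raise ConfigError(f"unknown cv.mode {self.cv.mode!r}")
        if not self.filter.cutoff_hz > 0:
            raise ConfigError("filter.cutoff_hz must be positive")
        if self.filter.order < 1:
            raise ConfigError("filter.order must be >= 1")
        if not self.contacts.min_separation_s > 0:
            raise ConfigError("contacts.min_separation_s must be positive")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mpf_band_hz"] = list(self.mpf_band_hz)
        return d

    def hash(self) -> str:
        """Stable hash of the configuration for provenance headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_SECTION_FIELDS = {
    "filter": FilterConfig,
    "contacts": ContactConfig,
    "cv": CvConfig,
}
_TOP_KEYS = {
    "filter", "contacts", "window_len_samples", "mpf_band_hz",
    "remove_mean", "positive_label", "cv", "models",
}


def default_config() -> RunConfig:
    return RunConfig().validate()


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config; unspecified keys take protocol defaults."""
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> RunConfig:
    cfg = RunConfig()
    for key, value in doc.items():
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown config key {key!r}; valid keys: {sorted(_TOP_KEYS)}")
        if key in _SECTION_FIELDS:
            cls = _SECTION_FIELDS[key]
            section = getattr(cfg, key)
            valid = set(cls.__dataclass_fields__)
            if not isinstance(value, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            for k2, v2 in value.items():
                if k2 not in valid:
                    raise ConfigError(
                        f"unknown key {k2!r} in section {key!r}; valid keys: {sorted(valid)}"
                    )
                setattr(section, k2, v2)
        elif key == "mpf_band_hz":
            if not (isinstance(value, (list, tuple)) and len(value) == 2):
                raise ConfigError("mpf_band_hz must be a 2-element sequence")
            cfg.mpf_band_hz = (float(value[0]), float(value[1]))
        elif key == "models":
            if not isinstance(value, dict):
                raise ConfigError("models must be a mapping of model name to parameters")
            cfg.models = value
        else:
            setattr(cfg, key, value)
    return cfg.validate()
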