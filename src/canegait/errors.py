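"""Typed exceptions for the cane-IMU gait pipeline.

Every rejection of an input (malformed file, unusable trial, degenerate
sample) raises one of these, never a bare ValueError, so callers can
account for exclusions per reason.
"""


class CaneGaitError(Exception):
    """Base class for all package errors."""


class ConfigError(CaneGaitError):
    """Run configuration is malformed or violates an invariant."""


class FormatError(CaneGaitError):
    """An on-disk artifact does not conform to the documented dialect."""


class DataError(CaneGaitError):
    """Well-formed file whose contents are unusable (gaps, NaN, too short)."""


class RateMismatchError(DataError):
    """Inferred sample rate disagrees with the declared rate by > 1 %."""


class NoContactError(DataError):
    """No cane ground contact detected; the trial is unusable."""


class ShortTrialError(DataError):
    """Recording too short to hold the analysis window after the first contact."""


class TooFewCyclesError(DataError):
    """Fewer than two contacts in the window; no complete gait cycle."""


class ZeroPowerError(DataError):
    """No spectral power inside the analysis band; MPF undefined."""


class DegenerateSampleError(DataError):
    """Statistic undefined on this sample (e.g. all values identical)."""


class SingleClassFoldError(DataError):
    """A training split contains one class only; re-seed the fold split."""
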