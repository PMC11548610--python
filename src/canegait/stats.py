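"""Nonparametric two-group comparison of gait features.

The univariate protocol: a Shapiro–Wilk normality screen per feature
and group, then a Mann–Whitney U test between frail and robust trials
with the asymptotic (normal-approximation) two-sided p-value, and the
rank effect size r = |Z|/sqrt(N) banded as small (0.1 <= r < 0.3),
moderate (0.3 <= r < 0.5) or large (r >= 0.5).

The normal approximation uses the tie-corrected variance and no
continuity correction, matching common statistical-package defaults.
An exact permutation p (full enumeration) is provided for small
samples as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DataError, DegenerateSampleError
from .io import FEATURE_COLUMNS


@dataclass
class NormalityResult:
    feature: str
    group: str
    W: float
    p_value: float


@dataclass
class MannWhitneyResult:
    U: float       # min(U1, U2)
    Z: float       # signed, from U1 (first sample)
    p_two_sided: float


@dataclass
class GroupComparison:
    feature: str
    n1: int
    n2: int
    median1: float
    median2: float
    U: float
    Z: float
    p_two_sided: float
    r: float
    magnitude: str
    significant: bool


def shapiro_wilk(x, feature: str = "", group: str = "") -> NormalityResult:
    """Shapiro–Wilk normality screen (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise DataError(f"Shapiro–Wilk requires 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("Shapiro–Wilk undefined for a constant sample")
    W, p = sstats.shapiro(x)
    return NormalityResult(feature=feature, group=group, W=float(W), p_value=float(p))


def _rank_sums(x: np.ndarray, y: np.ndarray):
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sstats.rankdata(combined)  # midranks for ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, ranks, n1, n2


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Mann–Whitney U with tie-corrected normal approximation.

    Z from the rank sums without continuity correction; two-sided p from
    the normal tail. U is reported as min(U1, U2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise DataError("both samples must be non-empty")
    u1, ranks, n1, n2 = _rank_sums(x, y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        raise DegenerateSampleError("all observations tied across both groups")
    z = (u1 - mu) / np.sqrt(var)
    p = min(1.0, 2.0 * sstats.norm.sf(abs(z)))
    u_min = min(u1, n1 * n2 - u1)
    return MannWhitneyResult(U=float(u_min), Z=float(z), p_two_sided=float(p))


def exact_mann_whitney_p(x, y, max_n: int = 16, mid_p: bool = False) -> float:
    """Exact two-sided permutation p for the U statistic (full enumeration).

    Enumerates all C(n1+n2, n1) group labelings of the pooled sample and
    counts those whose min(U1, U2) is at most the observed one. With
    ``mid_p`` the labelings attaining the observed value contribute half
    their mass — the discrete convention comparable to a continuous
    (normal-approximation) tail. Intended as an oracle for small samples
    (n1+n2 <= ``max_n``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    if n > max_n:
        raise DataError(f"exact enumeration limited to n <= {max_n}, got {n}")
    ranks = sstats.rankdata(np.concatenate([x, y]))
    offset = n1 * (n1 + 1) / 2.0
    u_obs = min((u := ranks[:n1].sum() - offset), n1 * n2 - u)
    below = at = 0
    for idx in combinations(range(n), n1):
        u1 = ranks[list(idx)].sum() - offset
        u_min = min(u1, n1 * n2 - u1)
        if u_min <= u_obs - 1e-9:
            below += 1
        elif u_min <= u_obs + 1e-9:
            at += 1
    total = comb(n, n1)
    if mid_p:
        return min(1.0, (below + 0.5 * at) / total)
    return (below + at) / total


def effect_size_r(z: float, n_total: int) -> float:
    """Rank effect size r = |Z| / sqrt(N)."""
    if n_total < 2:
        raise DataError("need n_total >= 2")
    return abs(z) / np.sqrt(n_total)


def classify_effect(r: float) -> str:
    """Band an effect size: <0.1 negligible, then small/moderate/large."""
    if r < 0:
        raise DataError("effect size r must be >= 0")
    if r < 0.1:
        return "negligible"
    if r < 0.3:
        return "small"
    if r < 0.5:
        return "moderate"
    return "large"


def compare_groups(
    table: pd.DataFrame,
    label_col: str = "frail_label",
    feature_cols=None,
    group1: str = "frail",
    group2: str = "robust",
    alpha: float = 0.05,
):
    """Per-feature Mann–Whitney comparison between the two groups.

    Returns ``(comparisons, normality)`` DataFrames: one row per feature
    with U, Z, p, r, magnitude and a significance flag at ``alpha``; and
    one Shapiro–Wilk row per (feature, group). No multiple-testing
    correction is applied across features (protocol choice); treat the
    per-feature flags accordingly.
    """
    if label_col not in table.columns:
        raise DataError(f"label column {label_col!r} missing from table")
    feature_cols = list(feature_cols or FEATURE_COLUMNS)
    g1 = table[table[label_col] == group1]
    g2 = table[table[label_col] == group2]
    if len(g1) == 0 or len(g2) == 0:
        raise DataError(f"both groups must be non-empty ({group1}: {len(g1)}, {group2}: {len(g2)})")

    comparisons = []
    normality = []
    for feat in feature_cols:
        x = g1[feat].to_numpy(dtype=float)
        y = g2[feat].to_numpy(dtype=float)
        res = mann_whitney_u(x, y)
        r = effect_size_r(res.Z, len(x) + len(y))
        comparisons.append(GroupComparison(
            feature=feat, n1=len(x), n2=len(y),
            median1=float(np.median(x)), median2=float(np.median(y)),
            U=res.U, Z=res.Z, p_two_sided=res.p_two_sided,
            r=r, magnitude=classify_effect(r),
            significant=bool(res.p_two_sided < alpha),
        ))
        for group, sample in ((group1, x), (group2, y)):
            try:
                normality.append(shapiro_wilk(sample, feature=feat, group=group))
            except DegenerateSampleError:
                normality.append(NormalityResult(feature=feat, group=group,
                                                 W=float("nan"), p_value=float("nan")))
    comp_df = pd.DataFrame([vars(c) for c in comparisons])
    norm_df = pd.DataFrame([vars(nr) for nr in normality])
    return comp_df, norm_df
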