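"""Retest-reliability and methodological-consistency statistics.

The central quantity is ICC(A,1): the single-measure, absolute-agreement
intraclass correlation from a two-way random-effects ANOVA,

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n),

with MSR/MSC/MSE the row (subject), column (session) and error mean squares
and k the number of sessions (here 2).  Confidence intervals use the
standard F-based construction.  ICCs below .50 are *poor*, [.50, .75)
*moderate*, [.75, .90) *good*, and >= .90 *excellent*.

Family averages (durations, occurrences, coverages across types; transitions
across type pairs) use Fisher z-averaging: correlations are atanh-
transformed, averaged, and back-transformed.  Differences between two
averaged correlations are tested with the z-test for independent
correlations, z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import TemplateSet
from .errors import InvalidDataError, MontageError, UndefinedStatisticError
from .interpolate import spherical_spline_resample
from .maps import Topography, spatial_correlation

__all__ = [
    "ICCResult",
    "icc_agreement",
    "icc_category",
    "fisher_average",
    "corr_diff_ztest",
    "map_reliability",
    "assign_interval_groups",
    "reliability_report",
    "FAMILIES",
]

#: characteristic families averaged in reports
FAMILIES = ("duration", "occurrence", "coverage", "transition")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    undefined: bool = False


def icc_agreement(x: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1) for an ``n x k`` table of paired measurements (k raters/sessions).

    Rows with any missing value are dropped (their count is reflected in the
    returned ``n``).  Needs at least 3 complete rows.  With zero total
    variance the ICC is undefined and flagged.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InvalidDataError("need an n x k table with k >= 2")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise InvalidDataError(f"need >= 3 complete pairs, got {n}")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    sst = float(np.sum((x - grand) ** 2))
    if sst == 0:
        warnings.warn("zero total variance: ICC undefined")
        return ICCResult(np.nan, np.nan, np.nan, n, undefined=True)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        warnings.warn("degenerate mean squares: ICC undefined")
        return ICCResult(np.nan, np.nan, np.nan, n, undefined=True)
    icc = (msr - mse) / denom
    # F-based CI (McGraw & Wong construction for single-measure agreement)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lo, hi = np.nan, np.nan
    return ICCResult(float(icc), float(lo), float(hi), n)


def icc_category(icc: float) -> str:
    """Reliability category: poor < .50 <= moderate < .75 <= good < .90 <= excellent."""
    if np.isnan(icc):
        return "undefined"
    if icc >= 0.90:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.50:
        return "moderate"
    return "poor"


def fisher_average(values: Iterable[float]) -> float:
    """Fisher z-average of correlations: ``tanh(mean(atanh(r)))``.

    Values at exactly +/-1 are clamped to 1 - 1e-12 in magnitude (warning);
    NaNs are dropped.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan")
    if np.any(np.abs(v) > 1):
        raise InvalidDataError("correlations must lie in [-1, 1]")
    if np.any(np.abs(v) == 1):
        warnings.warn("correlation of magnitude 1 clamped for Fisher averaging")
        v = np.clip(v, -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(v))))


def corr_diff_ztest(
    r1: float, n1: int, r2: float, n2: int, alternative: str = "greater"
) -> tuple[float, float, float]:
    """z-test for the difference of two independent correlations.

    Returns ``(z, p_one_sided, p_two_sided)``; the one-sided p follows
    ``alternative`` ('greater': H1 is r1 > r2, 'less': r1 < r2).
    """
    if n1 < 4 or n2 < 4:
        raise InvalidDataError("need n >= 4 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise InvalidDataError("correlations must have magnitude < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    if alternative == "greater":
        p1 = float(sps.norm.sf(z))
    elif alternative == "less":
        p1 = float(sps.norm.cdf(z))
    else:
        raise InvalidDataError("alternative must be 'greater' or 'less'")
    p2 = float(2 * sps.norm.sf(abs(z)))
    return float(z), p1, p2


def map_reliability(
    set1: TemplateSet, set2: TemplateSet
) -> tuple[dict[str, float], np.ndarray]:
    """Per-type polarity-invariant spatial correlations between two sorted sets.

    Both sets must carry the same labels in the same order (sort first).  If
    montages differ, ``set2`` is resampled to ``set1``'s montage.  Returns the
    per-type correlations and the full K x K cross-correlation matrix (rows =
    set1 types, columns = set2 types), useful for confusion analyses between
    similar types such as C and C'.
    """
    if set1.labels != set2.labels:
        raise InvalidDataError("template sets must carry identical labels (sort first)")
    t2 = set2.topographies
    if set1.montage != set2.montage:
        t2 = [spherical_spline_resample(t, set1.montage) for t in t2]
    t1 = set1.topographies
    K = set1.K
    cross = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            cross[i, j] = spatial_correlation(t1[i], t2[j], polarity_invariant=True)
    per_type = {lab: float(cross[i, i]) for i, lab in enumerate(set1.labels)}
    return per_type, cross


_INTERVAL_EDGES = (7, 30, 90, 180)


def assign_interval_groups(interval_days: Sequence[float] | np.ndarray) -> np.ndarray:
    """Group ids 1..5 for day-pair intervals: 1-7, 8-30, 31-90, 91-180, >=181."""
    d = np.asarray(interval_days, dtype=float)
    if np.any(d < 1):
        raise InvalidDataError("intervals must be >= 1 day")
    return np.searchsorted(_INTERVAL_EDGES, d, side="left") + 1


def _family_of(column: str) -> str | None:
    for fam in FAMILIES:
        if column.startswith(fam + "_"):
            return fam
    return None


def reliability_report(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    key: str = "subject",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ICC table for two paired condition tables of microstate characteristics.

    ``table1``/``table2`` are wide per-recording tables (one row per subject,
    characteristic columns as produced by ``stats_to_row``), paired on
    ``key``.  Per characteristic, pairs missing either value are dropped
    (count reported in ``n``).  The returned long table has one row per
    characteristic plus one ``average_<family>`` row per family, whose ICC is
    the Fisher z-average of the family members' ICCs.
    """
    merged = table1.merge(table2, on=key, suffixes=("_1", "_2"))
    if len(merged) < 3:
        raise InvalidDataError("need at least 3 shared subjects")
    mean_chars = ("explained_variance", "mean_duration", "mean_occurrence", "mean_gfp")
    chars = [c for c in table1.columns
             if c != key and c in table2.columns
             and (_family_of(c) is not None or c in mean_chars)]
    rows = []
    for c in chars:
        pair = merged[[f"{c}_1", f"{c}_2"]].to_numpy(dtype=float)
        complete = pair[~np.isnan(pair).any(axis=1)]
        if complete.shape[0] < 3:
            warnings.warn(f"characteristic {c}: fewer than 3 complete pairs, skipped")
            continue
        res = icc_agreement(complete, alpha=alpha)
        rows.append({
            "characteristic": c,
            "family": _family_of(c) or "mean",
            "icc": res.icc,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "n": res.n,
            "category": icc_category(res.icc),
        })
    out = pd.DataFrame(rows)
    avg_rows = []
    for fam in FAMILIES:
        sub = out[out["family"] == fam]
        if len(sub) == 0:
            continue
        avg = fisher_average(sub["icc"].to_numpy())
        avg_rows.append({
            "characteristic": f"average_{fam}",
            "family": fam,
            "icc": avg,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "n": int(sub["n"].min()),
            "category": icc_category(avg),
        })
    return pd.concat([out, pd.DataFrame(avg_rows)], ignore_index=True)
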