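"""Microstate characteristics derived from a continuous label sequence.

For each microstate type: *duration* (mean uninterrupted segment length in
ms), *occurrence* (segment onsets per second of assigned time), *coverage*
(percent of assigned samples), and the pairwise *transition statistic* —
the percentage excess of observed over occurrence-expected transition rate,

    transitions = (observed/s - expected/s) / (expected/s) * 100,

so a value of 10 means a transition happened 10% more often than expected
from the two types' occurrences alone.  Type-independent characteristics:
percent explained variance, mean duration, mean occurrence, and mean GFP
across types.

"Assigned time" (samples not labeled UNASSIGNED) is the denominator for all
rates and coverages.  Boundary-truncated segments are included in duration
and occurrence counts — short resting recordings make exclusion wasteful —
but carry a flag for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import TemplateSet
from .errors import InvalidDataError, UndefinedStatisticError
from .fitting import UNASSIGNED, LabelSequence, _corr_matrix
from .maps import Recording

__all__ = [
    "Segment",
    "MicrostateStats",
    "extract_segments",
    "compute_basic_stats",
    "compute_transitions",
    "transition_statistic",
    "explained_variance",
    "mean_gfp",
    "compute_stats",
    "stats_to_row",
]


def transition_statistic(observed_per_s: float, expected_per_s: float) -> float:
    """Percent excess of an observed over an expected transition rate.

    ``100 * (observed - expected) / expected``: e.g. 3.3 observed vs 3.0
    expected transitions per second gives 10 — that pair of types switched
    10% more often than their occurrences alone predict.
    """
    if expected_per_s <= 0:
        raise UndefinedStatisticError("transition statistic undefined for zero expected rate")
    return 100.0 * (observed_per_s - expected_per_s) / expected_per_s


@dataclass(frozen=True)
class Segment:
    """A maximal run of one label; truncated if cut by a recording edge or
    an UNASSIGNED gap."""

    label: int
    start: int
    length: int
    truncated: bool


@dataclass
class MicrostateStats:
    """All characteristics of one label sequence (class order = template order)."""

    labels: tuple[str, ...]
    durations_ms: np.ndarray  # (K,), NaN for absent classes
    occurrences: np.ndarray  # (K,), per second
    coverages: np.ndarray  # (K,), percent
    transitions: np.ndarray  # (K, K), percent excess; NaN diagonal/undefined
    explained_variance: float | None = None  # percent
    mean_duration_ms: float = np.nan
    mean_occurrence: float = np.nan
    mean_gfp: float | None = None  # µV
    total_time_s: float = np.nan  # assigned time


def extract_segments(seq: LabelSequence) -> list[Segment]:
    """Run-length encode the sequence; UNASSIGNED runs break and are dropped."""
    lab = seq.labels
    n = lab.shape[0]
    segs: list[Segment] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and lab[j + 1] == lab[i]:
            j += 1
        if lab[i] != UNASSIGNED:
            truncated = (
                i == 0 or j == n - 1 or lab[i - 1] == UNASSIGNED or lab[j + 1] == UNASSIGNED
            )
            segs.append(Segment(int(lab[i]), i, j - i + 1, truncated))
        i = j + 1
    return segs


def compute_basic_stats(seq: LabelSequence) -> MicrostateStats:
    """Durations, occurrences, coverages and their unweighted means.

    Per class: duration = mean segment length (ms); occurrence = number of
    segments per second of assigned time; coverage = percent of assigned
    samples.  Absent classes get NaN duration and zero occurrence/coverage;
    the type-independent means run over classes present only.
    """
    segs = extract_segments(seq)
    if not segs:
        raise UndefinedStatisticError("no assigned segments in sequence")
    K = seq.templates.K
    assigned_samples = int(np.sum(seq.labels != UNASSIGNED))
    total_s = assigned_samples / seq.srate
    durations = np.full(K, np.nan)
    occurrences = np.zeros(K)
    coverages = np.zeros(K)
    for k in range(K):
        lens = [s.length for s in segs if s.label == k]
        if lens:
            durations[k] = np.mean(lens) / seq.srate * 1000.0
            occurrences[k] = len(lens) / total_s
            coverages[k] = 100.0 * sum(lens) / assigned_samples
    present = ~np.isnan(durations)
    return MicrostateStats(
        labels=seq.templates.labels,
        durations_ms=durations,
        occurrences=occurrences,
        coverages=coverages,
        transitions=np.full((K, K), np.nan),
        mean_duration_ms=float(np.mean(durations[present])),
        mean_occurrence=float(np.mean(occurrences[present])),
        total_time_s=total_s,
    )


def compute_transitions(seq: LabelSequence) -> np.ndarray:
    """K x K matrix of the transition statistic (percent excess).

    ``observed[j, k]`` is the rate of direct j->k segment boundaries per
    second of assigned time (boundaries across UNASSIGNED gaps do not count);
    ``expected[j, k] = occ_j * occ_k / sum_{m != j} occ_m`` distributes each
    type's exits proportionally to the other types' occurrences.  Cells with
    zero expected rate are NaN (with a warning); the diagonal is NaN.
    """
    segs = extract_segments(seq)
    if len(segs) < 2:
        raise InvalidDataError("need at least 2 segments for transitions")
    K = seq.templates.K
    assigned_samples = int(np.sum(seq.labels != UNASSIGNED))
    total_s = assigned_samples / seq.srate
    occ = np.zeros(K)
    for k in range(K):
        occ[k] = sum(1 for s in segs if s.label == k) / total_s
    counts = np.zeros((K, K))
    for a, b in zip(segs[:-1], segs[1:]):
        if a.start + a.length == b.start:  # direct boundary, no gap
            counts[a.label, b.label] += 1
    observed = counts / total_s
    out = np.full((K, K), np.nan)
    n_zero = 0
    for j in range(K):
        denom = occ.sum() - occ[j]
        for k in range(K):
            if k == j:
                continue
            expected = occ[j] * occ[k] / denom if denom > 0 else 0.0
            if expected > 0:
                out[j, k] = transition_statistic(observed[j, k], expected)
            else:
                n_zero += 1
    if n_zero:
        warnings.warn(f"{n_zero} transition cell(s) undefined (zero expected rate)")
    return out


def explained_variance(rec: Recording, seq: LabelSequence, templates: TemplateSet) -> float:
    """Percent of GFP-weighted map variance captured by the assigned templates.

    ``100 * sum_t (gfp_t * r_t)**2 / sum_t gfp_t**2`` over assigned samples,
    with ``r_t`` the polarity-invariant correlation between the sample map
    and its assigned template.
    """
    assigned = seq.labels != UNASSIGNED
    if not np.any(assigned):
        raise UndefinedStatisticError("explained variance undefined: all samples unassigned")
    from .fitting import _templates_for

    templates = _templates_for(rec, templates)
    R, gfp = _corr_matrix(rec, templates)
    t = np.flatnonzero(assigned)
    r = np.abs(R[t, seq.labels[t]])
    denom = float(np.sum(gfp[t] ** 2))
    if denom == 0:
        raise UndefinedStatisticError("explained variance undefined: zero GFP")
    return 100.0 * float(np.sum((gfp[t] * r) ** 2)) / denom


def mean_gfp(rec: Recording, seq: LabelSequence) -> float:
    """Unweighted mean over classes of the mean GFP of that class's samples."""
    from .maps import gfp_curve

    assigned = seq.labels != UNASSIGNED
    if not np.any(assigned):
        raise UndefinedStatisticError("mean GFP undefined: all samples unassigned")
    g = gfp_curve(rec)
    per_class = [
        float(np.mean(g[seq.labels == k]))
        for k in range(seq.templates.K)
        if np.any(seq.labels == k)
    ]
    return float(np.mean(per_class))


def compute_stats(rec: Recording, seq: LabelSequence,
                  templates: TemplateSet | None = None) -> MicrostateStats:
    """All characteristics of a fitted recording in one object."""
    templates = templates if templates is not None else seq.templates
    st = compute_basic_stats(seq)
    if len(extract_segments(seq)) >= 2:
        st.transitions = compute_transitions(seq)
    st.explained_variance = explained_variance(rec, seq, templates)
    st.mean_gfp = mean_gfp(rec, seq)
    return st


def stats_to_row(st: MicrostateStats, **meta) -> pd.Series:
    """Flatten stats into one wide row (5 durations, 5 occurrences, 5
    coverages, K*(K-1) transitions, 4 mean characteristics + metadata)."""
    row: dict[str, float | str] = dict(meta)
    for i, lab in enumerate(st.labels):
        row[f"duration_{lab}"] = st.durations_ms[i]
        row[f"occurrence_{lab}"] = st.occurrences[i]
        row[f"coverage_{lab}"] = st.coverages[i]
    for i, a in enumerate(st.labels):
        for j, b in enumerate(st.labels):
            if i != j:
                row[f"transition_{a}_to_{b}"] = st.transitions[i, j]
    row["explained_variance"] = st.explained_variance
    row["mean_duration"] = st.mean_duration_ms
    row["mean_occurrence"] = st.mean_occurrence
    row["mean_gfp"] = st.mean_gfp
    row["total_time_s"] = st.total_time_s
    return pd.Series(row)
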