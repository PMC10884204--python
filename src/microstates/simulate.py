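"""Synthetic microstate-structured EEG with known ground truth.

The generator emulates the signal structure that microstate analysis
assumes in eyes-closed resting EEG:

* K quasi-dipolar template topographies (potential = cosine of the angle
  between each electrode position and a random dipole axis);
* a semi-Markov state sequence — the next state is drawn from a transition
  matrix (uniform off-diagonal by default) and dwell times are
  gamma-distributed with a per-class mean in the tens of milliseconds;
* an oscillatory carrier (10 Hz by default, random phase per segment) whose
  rectified envelope produces GFP peaks roughly every half cycle, as alpha
  does;
* average-referenced spatial Gaussian noise scaled to a stated SNR at the
  envelope maxima (SNR = template GFP / expected noise GFP).

``simulate_cohort`` adds the subject/session structure of a retest design:
each subject carries trait values (per-class mean dwell durations) drawn
around the population mean with a between-subject SD, each session realizes
them with a within-subject SD, so the designed intraclass correlation of the
trait is ``between**2 / (between**2 + within**2)``.  Subjects can also carry
slightly rotated ("jittered") copies of the population templates, which is
what makes grand-mean and individual fitting genuinely different.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clustering import CANONICAL_LABELS_5, TemplateSet
from .errors import GenerationError, InvalidDataError
from .maps import Montage, Recording, _ref

__all__ = [
    "GroundTruth",
    "CohortDesign",
    "CohortData",
    "make_templates",
    "simulate_recording",
    "simulate_cohort",
]


@dataclass(frozen=True)
class GroundTruth:
    """Realized (not nominal) statistics of one simulated recording."""

    templates: TemplateSet
    label_sequence: np.ndarray  # true class per sample
    durations_ms: np.ndarray  # (K,) realized mean dwell time
    occurrences: np.ndarray  # (K,) realized onsets per second
    coverages: np.ndarray  # (K,) realized percent of samples
    transition_matrix: np.ndarray  # (K, K) realized probabilities, zero diagonal


@dataclass(frozen=True)
class CohortDesign:
    """Study conditions for a simulated retest cohort.

    Durations are the manipulated characteristic: every subject has a trait
    per-class mean dwell duration ~ Normal(``mean_duration_ms``,
    ``between_subject_sd_ms``), realized per session with
    ``within_subject_sd_ms``.  The designed ICC of that trait is
    ``between**2 / (between**2 + within**2)``.
    """

    n_subjects: int = 20
    n_sessions: int = 2
    duration_s: float = 120.0
    srate: float = 500.0
    K: int = 5
    mean_duration_ms: float = 60.0
    gamma_shape: float = 4.0
    between_subject_sd_ms: float = 8.0
    within_subject_sd_ms: float = 4.0
    snr: float = 4.0
    oscillation_hz: float = 10.0
    template_jitter_r: float = 0.9  # min |r| of subject maps to population maps; 1 = none
    amplitude: float = 10.0  # µV scale of the oscillatory signal
    seed: int = 0

    def __post_init__(self):
        if self.between_subject_sd_ms < 0 or self.within_subject_sd_ms < 0:
            raise InvalidDataError("variance components must be >= 0")
        if self.snr <= 0 or self.gamma_shape <= 0 or self.mean_duration_ms <= 0:
            raise InvalidDataError("snr, gamma_shape and mean_duration_ms must be > 0")
        if not (0 < self.template_jitter_r <= 1):
            raise InvalidDataError("template_jitter_r must be in (0, 1]")

    @property
    def true_icc(self) -> float:
        """Designed ICC of the duration trait; NaN if both SDs are zero."""
        b2 = self.between_subject_sd_ms**2
        w2 = self.within_subject_sd_ms**2
        if b2 + w2 == 0:
            warnings.warn("both variance components are zero: designed ICC undefined")
            return float("nan")
        return b2 / (b2 + w2)


@dataclass(frozen=True)
class CohortData:
    """Simulated cohort: recordings with ground truth plus the design's truth."""

    recordings: list[Recording]
    ground_truths: list[GroundTruth]
    subject_templates: dict[str, TemplateSet]
    traits: pd.DataFrame  # subject, class, trait duration (ms)
    session_params: pd.DataFrame  # subject, session, class, duration (ms)
    population_templates: TemplateSet
    design: CohortDesign
    true_icc: float


def make_templates(
    montage: Montage,
    K: int = 5,
    min_pairwise_sep: float = 0.3,
    seed: int | None = None,
    max_tries: int = 2000,
) -> TemplateSet:
    """K random quasi-dipolar, unit-norm, average-referenced template maps.

    Each map is the cosine of the angle between electrode positions and a
    random dipole axis.  Axes are redrawn until all pairwise polarity-
    invariant correlations are at most ``1 - min_pairwise_sep``.
    """
    if K < 1:
        raise InvalidDataError("K must be >= 1")
    if not (0 <= min_pairwise_sep < 1):
        raise InvalidDataError("min_pairwise_sep must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pos = montage.positions

    def draw() -> np.ndarray:
        for _ in range(max_tries):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            v = _ref(pos @ axis)
            if np.linalg.norm(v) > 1e-9:
                return v / np.linalg.norm(v)
        raise GenerationError("could not draw a non-degenerate dipolar map")

    maps: list[np.ndarray] = []
    for _ in range(K):
        for attempt in range(max_tries):
            v = draw()
            if all(abs(v @ m) <= 1 - min_pairwise_sep for m in maps):
                maps.append(v)
                break
        else:
            raise GenerationError(
                f"could not place {K} maps with min_pairwise_sep={min_pairwise_sep}"
            )
    labels = CANONICAL_LABELS_5 if K == 5 else tuple(f"MS{i + 1}" for i in range(K))
    return TemplateSet(np.stack(maps), montage, labels, level="grand-mean")


def _jitter_templates(ts: TemplateSet, min_r: float, rng: np.random.Generator) -> TemplateSet:
    """Rotate each map toward a random direction so that |r| to the original
    lies in [min_r, 1]."""
    if min_r >= 1.0:
        return ts
    out = []
    for u in ts.maps:
        g = _ref(rng.normal(size=u.shape))
        g -= (g @ u) * u
        g /= np.linalg.norm(g)
        r_target = rng.uniform(min_r, 1.0)
        v = r_target * u + np.sqrt(1 - r_target**2) * g
        out.append(v / np.linalg.norm(v))
    return TemplateSet(np.stack(out), ts.montage, ts.labels, level="individual-mean")


def _realized_truth(labels: np.ndarray, templates: TemplateSet, srate: float) -> GroundTruth:
    K = templates.K
    n = labels.shape[0]
    # run-length encode
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    seg_labels = labels[starts]
    seg_lens = ends - starts
    total_s = n / srate
    durations = np.full(K, np.nan)
    occurrences = np.zeros(K)
    coverages = np.zeros(K)
    for k in range(K):
        sel = seg_labels == k
        if np.any(sel):
            durations[k] = seg_lens[sel].mean() / srate * 1000.0
            occurrences[k] = sel.sum() / total_s
            coverages[k] = 100.0 * seg_lens[sel].sum() / n
    tm = np.zeros((K, K))
    for a, b in zip(seg_labels[:-1], seg_labels[1:]):
        tm[a, b] += 1
    rowsum = tm.sum(axis=1, keepdims=True)
    uniform = (np.ones((K, K)) - np.eye(K)) / max(K - 1, 1)
    tm = np.where(rowsum > 0, tm / np.where(rowsum > 0, rowsum, 1), uniform)
    np.fill_diagonal(tm, 0.0)
    tm = tm / tm.sum(axis=1, keepdims=True)
    return GroundTruth(templates, labels, durations, occurrences, coverages, tm)


def simulate_recording(
    templates: TemplateSet,
    design: CohortDesign,
    mean_durations_ms: np.ndarray | float | None = None,
    duration_s: float | None = None,
    srate: float | None = None,
    seed: int | np.random.SeedSequence | None = None,
    transition_matrix: np.ndarray | None = None,
    subject_id: str = "S0",
    session_id: str = "pre",
    day_id: str = "one",
) -> tuple[Recording, GroundTruth]:
    """One recording: semi-Markov microstate sequence x oscillation + noise.

    ``mean_durations_ms`` (scalar or per class) defaults to the design's
    population mean; the realized statistics reported in the returned
    :class:`GroundTruth` come from the actually generated label sequence.
    """
    duration_s = design.duration_s if duration_s is None else duration_s
    srate = design.srate if srate is None else srate
    if duration_s <= 0:
        raise InvalidDataError("duration_s must be > 0")
    K = templates.K
    mu = np.broadcast_to(
        np.asarray(design.mean_duration_ms if mean_durations_ms is None else mean_durations_ms,
                   dtype=float),
        (K,),
    ).copy()
    if np.any(mu <= 0):
        raise InvalidDataError("mean durations must be > 0")
    if transition_matrix is None:
        transition_matrix = (np.ones((K, K)) - np.eye(K)) / max(K - 1, 1)
    P = np.asarray(transition_matrix, dtype=float)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * srate))

    labels = np.empty(n, dtype=int)
    seg_bounds: list[tuple[int, int, int]] = []  # (start, end, class)
    t = 0
    state = int(rng.integers(K)) if K > 1 else 0
    while t < n:
        dur_ms = rng.gamma(design.gamma_shape, mu[state] / design.gamma_shape)
        length = max(1, int(round(dur_ms / 1000.0 * srate)))
        end = min(t + length, n)
        labels[t:end] = state
        seg_bounds.append((t, end, state))
        t = end
        if K > 1:
            state = int(rng.choice(K, p=P[state]))

    C = templates.montage.n_channels
    data = np.empty((C, n))
    tt = np.arange(n) / srate
    carrier = np.empty(n)
    for start, end, state in seg_bounds:
        phase = rng.uniform(0, 2 * np.pi)
        carrier[start:end] = np.sin(2 * np.pi * design.oscillation_hz * tt[start:end] + phase)
    amp = design.amplitude
    data = templates.maps[labels].T * (amp * carrier)

    # noise scaled so SNR at envelope maxima = template GFP / E[noise GFP]
    template_gfp = 1.0 / np.sqrt(C)  # unit-norm, average-referenced maps
    sigma = amp * template_gfp / design.snr * np.sqrt(C / (C - 1))
    noise = _ref(rng.normal(scale=sigma, size=(C, n)))
    rec = Recording(data + noise, srate, templates.montage,
                    subject_id=subject_id, session_id=session_id, day_id=day_id)
    return rec, _realized_truth(labels, templates, srate)


def simulate_cohort(
    templates: TemplateSet,
    design: CohortDesign,
    seed: int | None = None,
) -> CohortData:
    """Subjects x sessions cohort with a designed true ICC of durations.

    Per subject and class, a trait mean duration is drawn around the
    population mean with the between-subject SD; each session realizes it
    with the within-subject SD (floored at 10 ms).  Session order inside
    ``recordings``/``ground_truths`` is subject-major.  Subject template
    jitter (if enabled) is a subject-level trait: both sessions of a subject
    share the same jittered maps.
    """
    if design.n_subjects < 2 or design.n_sessions < 2:
        raise InvalidDataError("cohort needs >= 2 subjects and >= 2 sessions")
    root = np.random.SeedSequence(design.seed if seed is None else seed)
    ss_traits, ss_jitter, ss_rec = root.spawn(3)
    rng_traits = np.random.default_rng(ss_traits)
    rng_jitter = np.random.default_rng(ss_jitter)
    rec_seeds = ss_rec.spawn(design.n_subjects * design.n_sessions)

    K = templates.K
    session_names = [f"sess{j + 1}" for j in range(design.n_sessions)]
    recordings, truths = [], []
    subject_templates: dict[str, TemplateSet] = {}
    trait_rows, param_rows = [], []
    idx = 0
    for i in range(design.n_subjects):
        sid = f"S{i + 1:03d}"
        trait = design.mean_duration_ms + rng_traits.normal(
            scale=design.between_subject_sd_ms, size=K
        )
        trait = np.maximum(trait, 10.0)
        subject_templates[sid] = _jitter_templates(
            templates, design.template_jitter_r, rng_jitter
        )
        for k in range(K):
            trait_rows.append({"subject": sid, "class": templates.labels[k],
                               "trait_duration_ms": trait[k]})
        for j, sess in enumerate(session_names):
            sess_mu = trait + rng_traits.normal(scale=design.within_subject_sd_ms, size=K)
            sess_mu = np.maximum(sess_mu, 10.0)
            for k in range(K):
                param_rows.append({"subject": sid, "session": sess,
                                   "class": templates.labels[k],
                                   "duration_ms": sess_mu[k]})
            rec, gt = simulate_recording(
                subject_templates[sid], design, mean_durations_ms=sess_mu,
                seed=rec_seeds[idx], subject_id=sid, session_id=sess,
            )
            recordings.append(rec)
            truths.append(gt)
            idx += 1
    return CohortData(
        recordings=recordings,
        ground_truths=truths,
        subject_templates=subject_templates,
        traits=pd.DataFrame(trait_rows),
        session_params=pd.DataFrame(param_rows),
        population_templates=templates,
        design=design,
        true_icc=design.true_icc,
    )
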