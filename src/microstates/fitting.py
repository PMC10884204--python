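"""Back-fitting microstate templates to continuous EEG.

The continuous label sequence is obtained by labeling maps at GFP peaks with
the template of maximal polarity-invariant spatial correlation, spreading
labels to all samples by nearest-neighbor interpolation in time, and finally
applying temporal smoothing with a window/penalty scheme.

Two procedures are exposed:

* ``gm_fitting`` — label the recording directly with grand-mean templates.
* ``ind_fitting`` — first type-match the subject's own mean maps to the
  grand-mean templates, then label the recording with those subject maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import TemplateSet, sort_against_reference
from .errors import InvalidDataError
from .interpolate import spherical_spline_resample
from .maps import Recording, Topography, _ref, find_gfp_peaks, gfp_curve

__all__ = [
    "UNASSIGNED",
    "LabelSequence",
    "assign_peak_maps",
    "interpolate_labels",
    "smooth_labels",
    "gm_fitting",
    "ind_fitting",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class LabelSequence:
    """Per-sample microstate assignment with per-sample fit correlation."""

    labels: np.ndarray  # int, class index or UNASSIGNED
    fit_r: np.ndarray  # |spatial correlation| with the assigned template; NaN if unassigned
    srate: float
    templates: TemplateSet

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=int)
        r = np.asarray(self.fit_r, dtype=float)
        if lab.shape != r.shape or lab.ndim != 1:
            raise InvalidDataError("labels and fit_r must be matching 1-D arrays")
        assigned = lab != UNASSIGNED
        if np.any((lab[assigned] < 0) | (lab[assigned] >= self.templates.K)):
            raise InvalidDataError("label outside template range")
        if np.any((r[assigned] < -1e-9) | (r[assigned] > 1 + 1e-9)):
            raise InvalidDataError("fit_r must lie in [0, 1] where assigned")
        lab = lab.copy()
        lab.setflags(write=False)
        r = r.copy()
        r.setflags(write=False)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "fit_r", r)

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]


def _corr_matrix(rec: Recording, templates: TemplateSet) -> tuple[np.ndarray, np.ndarray]:
    """Signed correlation of every sample map with every template.

    Returns ``(R, gfp)`` with ``R`` shaped (n_samples, K); rows with zero
    spatial variance get all-zero correlations.
    """
    D = _ref(rec.data)  # (C, n)
    norms = np.linalg.norm(D, axis=0)
    gfp = norms / np.sqrt(D.shape[0])
    safe = np.where(norms > 0, norms, 1.0)
    R = (D / safe).T @ templates.maps.T
    R[norms == 0] = 0.0
    return R, gfp


def _templates_for(rec: Recording, templates: TemplateSet) -> TemplateSet:
    """Resample templates to the recording's montage if needed (never the data)."""
    if templates.montage == rec.montage:
        return templates
    maps = np.stack(
        [spherical_spline_resample(t, rec.montage).values for t in templates.topographies]
    )
    return TemplateSet(maps, rec.montage, templates.labels, level=templates.level,
                       gev=templates.gev)


def assign_peak_maps(
    rec: Recording,
    templates: TemplateSet,
    peaks: Sequence[int] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Label the maps at GFP-peak samples by maximal |spatial correlation|.

    Returns ``(labels, fit_r)`` over the peak samples only.  Ties within
    1e-12 go to the lowest template index (with a warning); a zero-variance
    peak map is left UNASSIGNED with a warning.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size and (peaks.min() < 0 or peaks.max() >= rec.n_samples):
        raise InvalidDataError("peak index out of range")
    templates = _templates_for(rec, templates)
    R, gfp = _corr_matrix(rec, templates)
    A = np.abs(R[peaks])  # (n_peaks, K)
    labels = np.argmax(A, axis=1)
    best = A[np.arange(peaks.size), labels]
    runner = np.partition(A, -2, axis=1)[:, -2] if templates.K > 1 else np.full(peaks.size, -np.inf)
    ties = (best - runner) <= 1e-12
    if np.any(ties & (best > 0)):
        warnings.warn(f"{int(np.sum(ties & (best > 0)))} peak map(s) tied between templates; "
                      "lowest index kept")
        tied_rows = np.flatnonzero(ties & (best > 0))
        labels[tied_rows] = np.argmax(A[tied_rows] >= (best[tied_rows, None] - 1e-12), axis=1)
        best = A[np.arange(peaks.size), labels]
    zero_var = gfp[peaks] == 0
    if np.any(zero_var):
        warnings.warn(f"{int(zero_var.sum())} zero-variance peak map(s) left unassigned")
        labels[zero_var] = UNASSIGNED
        best[zero_var] = np.nan
    return labels.astype(int), best


def interpolate_labels(
    peaks: Sequence[int] | np.ndarray,
    peak_labels: Sequence[int] | np.ndarray,
    n_samples: int,
    srate: float,
    templates: TemplateSet,
    peak_fit_r: Sequence[float] | np.ndarray | None = None,
) -> LabelSequence:
    """Spread peak labels to every sample by nearest labeled peak in time.

    Equidistant samples take the earlier peak's label.  With zero labeled
    peaks every sample is UNASSIGNED.
    """
    peaks = np.asarray(peaks, dtype=int)
    peak_labels = np.asarray(peak_labels, dtype=int)
    fit = (np.asarray(peak_fit_r, dtype=float) if peak_fit_r is not None
           else np.ones(peaks.size))
    keep = peak_labels != UNASSIGNED
    peaks, peak_labels, fit = peaks[keep], peak_labels[keep], fit[keep]
    labels = np.full(n_samples, UNASSIGNED, dtype=int)
    fit_r = np.full(n_samples, np.nan)
    if peaks.size:
        order = np.argsort(peaks)
        peaks, peak_labels, fit = peaks[order], peak_labels[order], fit[order]
        t = np.arange(n_samples)
        # index of nearest peak; ties -> earlier peak
        idx = np.searchsorted(peaks, t)
        idx_prev = np.clip(idx - 1, 0, peaks.size - 1)
        idx_next = np.clip(idx, 0, peaks.size - 1)
        d_prev = np.abs(t - peaks[idx_prev])
        d_next = np.abs(peaks[idx_next] - t)
        nearest = np.where(d_prev <= d_next, idx_prev, idx_next)
        labels = peak_labels[nearest]
        fit_r = fit[nearest]
    return LabelSequence(labels, fit_r, srate, templates)


def _neighbor_counts(labels: np.ndarray, K: int, half: int) -> np.ndarray:
    """N[t, k]: assigned samples labeled k within +/-half of t, excluding t."""
    n = labels.shape[0]
    N = np.zeros((n, K))
    onehot = np.zeros((n, K))
    assigned = labels != UNASSIGNED
    onehot[assigned, labels[assigned]] = 1.0
    cs = np.vstack([np.zeros((1, K)), np.cumsum(onehot, axis=0)])  # (n+1, K)
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    N = cs[hi] - cs[lo] - onehot
    return N


def _normalized_gfp(gfp: np.ndarray, assigned: np.ndarray) -> np.ndarray:
    """GFP divided by its RMS over assigned samples.

    Standardizing the amplitude makes the smoothing penalty dimensionless,
    so relabeling decisions are invariant to rescaling the recording.
    """
    rms = np.sqrt(np.mean(gfp[assigned] ** 2)) if np.any(assigned) else 1.0
    return gfp / (rms if rms > 0 else 1.0)


def smoothing_objective(
    labels: np.ndarray,
    R: np.ndarray,
    gfp: np.ndarray,
    penalty: float,
    half: int,
) -> float:
    """Total cost ``sum_t g_t^2 (1 - r_{t,l_t}^2) - penalty * N_{t,l_t}``
    with ``g`` the RMS-normalized GFP.

    Exposed so that the smoothing can be checked against independent exact
    minimization on short windows.
    """
    K = R.shape[1]
    N = _neighbor_counts(labels, K, half)
    assigned = labels != UNASSIGNED
    g = _normalized_gfp(gfp, assigned)
    t = np.flatnonzero(assigned)
    misfit = g[t] ** 2 * (1 - R[t, labels[t]] ** 2)
    return float(np.sum(misfit - penalty * N[t, labels[t]]))


def smooth_labels(
    rec: Recording,
    seq: LabelSequence,
    templates: TemplateSet | None = None,
    window_ms: float = 20.0,
    penalty: float = 1.0,
    max_iter: int = 100,
) -> LabelSequence:
    """Temporal smoothing of a label sequence (window/penalty scheme).

    Iteratively relabels each assigned sample ``t`` with the class ``k``
    minimizing ``g_t**2 * (1 - r_{t,k}**2) - penalty * N_{t,k}``, where ``g``
    is the GFP normalized by its RMS over assigned samples (making labels
    invariant to rescaling the recording) and ``N_{t,k}`` counts assigned
    samples labeled ``k`` within the smoothing window (+/- ``window_ms``/2
    around ``t``, excluding ``t`` itself), until the labeling is stable or
    ``max_iter`` sweeps have run.  Deterministic; UNASSIGNED samples are
    excluded from counts and never relabeled.  ``penalty = 0`` disables
    smoothing and returns the input sequence.
    """
    if window_ms < 0 or penalty < 0:
        raise InvalidDataError("window_ms and penalty must be >= 0")
    if penalty == 0:
        return seq
    templates = _templates_for(rec, templates if templates is not None else seq.templates)
    R, gfp = _corr_matrix(rec, templates)
    half = int(round(window_ms / 2.0 / 1000.0 * rec.srate))
    labels = seq.labels.copy()
    assigned = labels != UNASSIGNED
    K = templates.K
    g = _normalized_gfp(gfp, assigned)
    misfit = g[:, None] ** 2 * (1 - R**2)  # (n, K)
    for _ in range(max_iter):
        N = _neighbor_counts(labels, K, half)
        cost = misfit - penalty * N
        new = np.argmin(cost, axis=1)
        new[~assigned] = UNASSIGNED
        if np.array_equal(new, labels):
            break
        labels = new
    fit_r = np.full(labels.shape, np.nan)
    fit_r[assigned] = np.abs(R[assigned, labels[assigned]])
    return LabelSequence(labels, fit_r, seq.srate, templates)


def gm_fitting(
    rec: Recording,
    grand_templates: TemplateSet,
    min_peak_distance_ms: float = 0.0,
    window_ms: float = 20.0,
    penalty: float = 1.0,
) -> LabelSequence:
    """Grand-mean fitting: label the recording with group-level templates.

    Pipeline: GFP peaks -> peak labeling by |spatial correlation| ->
    nearest-neighbor interpolation -> temporal smoothing.
    """
    templates = _templates_for(rec, grand_templates)
    gfp = gfp_curve(rec)
    peaks = find_gfp_peaks(gfp, min_distance_ms=min_peak_distance_ms, srate=rec.srate)
    labels, fit = assign_peak_maps(rec, templates, peaks)
    seq = interpolate_labels(peaks, labels, rec.n_samples, rec.srate, templates, fit)
    return smooth_labels(rec, seq, templates, window_ms=window_ms, penalty=penalty)


def ind_fitting(
    rec: Recording,
    subject_templates: TemplateSet,
    grand_templates: TemplateSet,
    min_peak_distance_ms: float = 0.0,
    window_ms: float = 20.0,
    penalty: float = 1.0,
) -> LabelSequence:
    """Individual fitting: label with the subject's own type-matched maps.

    The subject's mean maps are first assigned microstate types by one-to-one
    matching against the grand-mean templates; the recording is then fitted
    with those subject maps instead of the grand means.
    """
    if subject_templates.K != grand_templates.K:
        raise InvalidDataError("subject and grand template sets must share K")
    sorted_subject = sort_against_reference(subject_templates, grand_templates)
    return gm_fitting(rec, sorted_subject, min_peak_distance_ms=min_peak_distance_ms,
                      window_ms=window_ms, penalty=penalty)
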