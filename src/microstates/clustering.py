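"""Polarity-invariant clustering of EEG maps into microstate templates.

Two algorithms are provided, both ignoring map polarity (a topography and its
sign flip count as the same microstate):

* **modified k-means** — iteratively assigns maps to the template with the
  highest squared spatial correlation and re-estimates each template as the
  first principal component of its assigned maps; restarted multiple times,
  best solution by global explained variance (GEV) kept.
* **AAHC** (atomize-and-agglomerate hierarchical clustering) — starts from
  singleton clusters and repeatedly dissolves the cluster contributing least
  to GEV, reassigning its members to the most similar remaining cluster.

On top of these, ``two_level_grand_mean`` aggregates per-subject template
sets into grand-mean templates under a one-to-one matching constraint, and
``grand_grand_mean_consistency`` quantifies agreement of several grand-mean
sets — the criterion used to pick the number of clusters.

GEV of a solution is ``sum_i (gfp_i * r_i)**2 / sum_i gfp_i**2`` where
``r_i`` is the spatial correlation between map *i* and its assigned template
and ``gfp_i`` the map's global field power: high-GFP maps count more.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidDataError, MontageError
from .interpolate import spherical_spline_resample
from .maps import Montage, Topography, _ref

__all__ = [
    "TemplateSet",
    "ClusterResult",
    "modified_kmeans",
    "aahc",
    "two_level_grand_mean",
    "grand_grand_mean_consistency",
    "sort_against_reference",
    "save_template_set",
    "load_template_set",
]

CANONICAL_LABELS_5 = ("A", "B", "C", "C'", "D")


@dataclass(frozen=True)
class TemplateSet:
    """K labeled microstate template maps (unit-norm, average-referenced)."""

    maps: np.ndarray  # (K, n_channels)
    montage: Montage
    labels: tuple[str, ...]
    level: str = "individual-mean"  # individual-mean | grand-mean | grand-grand-mean
    gev: float | None = None

    def __post_init__(self):
        m = np.asarray(self.maps, dtype=float)
        if m.ndim != 2 or m.shape[1] != self.montage.n_channels:
            raise InvalidDataError("template maps must be (K, n_channels)")
        if m.shape[0] < 1:
            raise InvalidDataError("need at least one template")
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != m.shape[0] or len(set(labels)) != len(labels):
            raise InvalidDataError("labels must be unique, one per map")
        m = _ref(m.T).T
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise InvalidDataError("zero template map")
        m = m / norms[:, None]
        m.setflags(write=False)
        object.__setattr__(self, "maps", m)
        object.__setattr__(self, "labels", labels)

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def topographies(self) -> list[Topography]:
        return [Topography(row, self.montage) for row in self.maps]


@dataclass(frozen=True)
class ClusterResult:
    templates: TemplateSet
    assignment: np.ndarray  # cluster index per input map
    polarity: np.ndarray  # +/-1 per input map
    gev: float


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _as_matrix(maps: Sequence[Topography] | np.ndarray, montage: Montage | None = None):
    """Rows = average-referenced maps; also returns GFP and unit-norm rows."""
    if isinstance(maps, np.ndarray):
        if montage is None:
            raise InvalidDataError("montage required when passing a bare array")
        X = np.asarray(maps, dtype=float)
    else:
        maps = list(maps)
        if not maps:
            raise InvalidDataError("no maps given")
        montage = maps[0].montage
        if any(t.montage != montage for t in maps):
            raise MontageError("all maps must share one montage")
        X = np.stack([t.values for t in maps])
    X = _ref(X.T).T
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise InvalidDataError("zero-variance map in input")
    gfp = norms / np.sqrt(X.shape[1])
    return X, X / norms[:, None], gfp, montage


def _first_pc(rows: np.ndarray, align_to: np.ndarray | None = None) -> np.ndarray:
    """Unit-norm first principal component of the row space (through zero)."""
    # eigenvector of the channel covariance sum_i x_i x_i^T
    cov = rows.T @ rows
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    if align_to is not None and v @ align_to < 0:
        v = -v
    elif align_to is None and v[np.argmax(np.abs(v))] < 0:
        v = -v  # deterministic sign convention
    return v / np.linalg.norm(v)


def _gev(gfp: np.ndarray, absr: np.ndarray) -> float:
    return float(np.sum((gfp * absr) ** 2) / np.sum(gfp**2))


def _default_labels(K: int) -> tuple[str, ...]:
    return tuple(f"MS{i + 1}" for i in range(K))


# ---------------------------------------------------------------------------
# modified k-means
# ---------------------------------------------------------------------------

def modified_kmeans(
    maps: Sequence[Topography] | np.ndarray,
    K: int,
    n_restarts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
    montage: Montage | None = None,
) -> ClusterResult:
    """Polarity-invariant modified k-means over maps.

    Each restart picks K distinct input maps as initial templates, then
    alternates (a) assigning every map to the template with maximal squared
    spatial correlation and (b) replacing each template with the first
    principal component of its assigned maps, until the relative GEV change
    drops below ``tol``.  The best of ``n_restarts`` runs by GEV is returned.
    """
    X, Xn, gfp, montage = _as_matrix(maps, montage)
    n = X.shape[0]
    if K > n:
        raise InvalidDataError(f"K={K} exceeds number of maps ({n})")
    child_seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        T = Xn[rng.choice(n, size=K, replace=False)].copy()
        gev_prev = -np.inf
        for _ in range(max_iter):
            R = Xn @ T.T  # (n, K) signed correlations
            assign = np.argmax(np.abs(R), axis=1)
            # re-seed empty clusters from the worst-fit map
            absr = np.abs(R[np.arange(n), assign])
            for k in range(K):
                if not np.any(assign == k):
                    worst = int(np.argmin(absr))
                    assign[worst] = k
                    absr[worst] = 1.0
            for k in range(K):
                T[k] = _first_pc(X[assign == k], align_to=T[k])
            R = Xn @ T.T
            assign = np.argmax(np.abs(R), axis=1)
            absr = np.abs(R[np.arange(n), assign])
            gev = _gev(gfp, absr)
            if gev - gev_prev < tol * max(gev_prev, 1e-12):
                gev_prev = gev
                break
            gev_prev = gev
        if best is None or gev_prev > best[0]:
            polarity = np.sign(R[np.arange(n), assign])
            polarity[polarity == 0] = 1
            best = (gev_prev, T.copy(), assign.copy(), polarity)
    gev, T, assign, polarity = best
    ts = TemplateSet(T, montage, _default_labels(K), level="individual-mean", gev=gev)
    return ClusterResult(ts, assign, polarity.astype(int), gev)


# ---------------------------------------------------------------------------
# AAHC
# ---------------------------------------------------------------------------

def aahc(
    maps: Sequence[Topography] | np.ndarray,
    K: int,
    montage: Montage | None = None,
) -> ClusterResult:
    """Atomize-and-agglomerate hierarchical clustering down to K clusters.

    Deterministic: starts from singletons; at each step the cluster whose
    members contribute least to GEV is dissolved, its maps are reassigned to
    the most similar remaining cluster map (polarity-invariant), and the
    receiving clusters' maps are re-estimated as first principal components.
    """
    X, Xn, gfp, montage = _as_matrix(maps, montage)
    n = X.shape[0]
    if K > n:
        raise InvalidDataError(f"K={K} exceeds number of maps ({n})")
    assign = np.arange(n)
    T = Xn.copy()  # cluster maps, one per active cluster id
    active = list(range(n))
    absr = np.ones(n)  # correlation of each map with its cluster map
    w2 = gfp**2
    while len(active) > K:
        # GEV contribution per active cluster
        contrib = {c: float(np.sum(w2[assign == c] * absr[assign == c] ** 2)) for c in active}
        victim = min(active, key=lambda c: (contrib[c], c))
        active.remove(victim)
        freed = np.flatnonzero(assign == victim)
        Tact = T[active]
        R = Xn[freed] @ Tact.T
        new = np.argmax(np.abs(R), axis=1)
        for j, i in zip(new, freed):
            assign[i] = active[j]
        # update receiving clusters and their members' correlations
        for c in set(active[j] for j in new):
            members = assign == c
            T[c] = _first_pc(X[members], align_to=T[c])
            absr[members] = np.abs(Xn[members] @ T[c])
    # compact cluster ids to 0..K-1 in order of appearance
    order = sorted(active)
    remap = {c: k for k, c in enumerate(order)}
    final_assign = np.array([remap[c] for c in assign])
    Tfinal = T[order]
    R = Xn @ Tfinal.T
    absr = np.abs(R[np.arange(n), final_assign])
    polarity = np.sign(R[np.arange(n), final_assign])
    polarity[polarity == 0] = 1
    gev = _gev(gfp, absr)
    ts = TemplateSet(Tfinal, montage, _default_labels(K), level="individual-mean", gev=gev)
    return ClusterResult(ts, final_assign, polarity.astype(int), gev)


# ---------------------------------------------------------------------------
# second-level (grand-mean) clustering
# ---------------------------------------------------------------------------

def _best_permutation(R2: np.ndarray) -> tuple[tuple[int, ...], float]:
    """Exhaustive one-to-one matching maximizing sum of R2[j, perm[j]].

    Deterministic lexicographic tie-break (first permutation in
    ``itertools.permutations`` order wins ties within 1e-9).
    """
    K = R2.shape[0]
    best_perm, best_val = None, -np.inf
    for perm in itertools.permutations(range(K)):
        val = sum(R2[j, perm[j]] for j in range(K))
        if val > best_val + 1e-9:
            best_perm, best_val = perm, val
    return best_perm, best_val


def two_level_grand_mean(
    subject_sets: Sequence[TemplateSet],
    K: int | None = None,
    method: str = "kmeans",
    n_restarts: int = 10,
    max_iter: int = 100,
    seed: int | None = None,
) -> tuple[TemplateSet, np.ndarray]:
    """Grand-mean templates across subjects with a one-to-one constraint.

    Subject template sets (all with the same K) are aggregated by alternating
    (a) matching each subject's maps one-to-one to the grand-mean slots by
    the permutation maximizing the summed squared spatial correlation
    (exhaustive over K!), and (b) updating each grand-mean map as the first
    principal component of its matched subject maps.  Initialization comes
    from running the chosen base clustering on the pooled subject maps;
    k-means initialization is multi-restart, best by mean shared variance.

    Returns the grand-mean :class:`TemplateSet` (its ``gev`` holds the mean
    shared variance, i.e. mean squared correlation between subject maps and
    their matched grand means) and an ``(n_subjects, K)`` permutation array:
    row *s*, slot *j* gives the index of subject *s*'s map matched to grand
    mean *j*.  Subjects contribute with equal weight (maps are unit-norm).
    """
    sets = list(subject_sets)
    if not sets:
        raise InvalidDataError("no subject template sets")
    Ks = {ts.K for ts in sets}
    if len(Ks) != 1:
        raise InvalidDataError(f"subjects have differing K: {sorted(Ks)}")
    if K is None:
        K = sets[0].K
    elif K != sets[0].K:
        raise InvalidDataError("requested K differs from subject sets' K")
    montage = sets[0].montage
    if any(ts.montage != montage for ts in sets):
        raise MontageError("subject sets must share one montage")
    S = len(sets)
    M = np.stack([ts.maps for ts in sets])  # (S, K, C) unit-norm

    pooled = M.reshape(S * K, -1)
    if method == "kmeans":
        init = modified_kmeans(pooled, K, n_restarts=n_restarts, seed=seed, montage=montage)
    elif method == "aahc":
        init = aahc(pooled, K, montage=montage)
    else:
        raise InvalidDataError(f"unknown method {method!r}")
    T = init.templates.maps.copy()

    perms = np.zeros((S, K), dtype=int)
    prev_msv = -np.inf
    for _ in range(max_iter):
        msv = 0.0
        for s in range(S):
            R2 = (T @ M[s].T) ** 2  # (K slots, K subject maps)
            perm, val = _best_permutation(R2)
            perms[s] = perm
            msv += val
        msv /= S * K
        for j in range(K):
            rows = M[np.arange(S), perms[:, j]]
            T[j] = _first_pc(rows, align_to=T[j])
        if msv - prev_msv < 1e-10:
            break
        prev_msv = msv
    ts = TemplateSet(T, montage, _default_labels(K), level="grand-mean", gev=float(msv))
    return ts, perms


def grand_grand_mean_consistency(
    grand_mean_sets: Sequence[TemplateSet],
    seed: int | None = None,
) -> tuple[TemplateSet, float]:
    """Agreement of several grand-mean sets via a grand-grand mean.

    Pools the given grand-mean sets into a grand-grand mean (same two-level
    procedure) and returns it along with the mean shared variance in percent:
    ``100 * mean of r**2`` between each set's maps and their matched
    grand-grand-mean maps.  This is the quantity compared across candidate
    cluster numbers to choose K.
    """
    sets = list(grand_mean_sets)
    if len(sets) == 1:
        warnings.warn("single grand-mean set: consistency is trivially 100%")
        only = sets[0]
        ts = TemplateSet(only.maps, only.montage, only.labels, level="grand-grand-mean", gev=1.0)
        return ts, 100.0
    ggm, _ = two_level_grand_mean(sets, seed=seed)
    ts = TemplateSet(ggm.maps, ggm.montage, ggm.labels, level="grand-grand-mean", gev=ggm.gev)
    return ts, 100.0 * float(ggm.gev)


def sort_against_reference(ts: TemplateSet, reference: TemplateSet) -> TemplateSet:
    """Reorder, relabel and sign-align a template set to match a reference.

    The one-to-one matching maximizes the summed squared spatial correlation
    (exhaustive over permutations, deterministic lexicographic tie-break with
    a warning on near-ties).  If montages differ, the set is first resampled
    to the reference montage via spherical splines for matching, but the
    returned maps stay on their original montage.
    """
    if ts.K != reference.K:
        raise InvalidDataError("template sets must have the same K")
    if ts.montage == reference.montage:
        Mcmp = ts.maps
    else:
        Mcmp = np.stack(
            [
                spherical_spline_resample(t, reference.montage).values
                for t in ts.topographies
            ]
        )
        norms = np.linalg.norm(Mcmp, axis=1)
        Mcmp = Mcmp / norms[:, None]
    R = reference.maps @ Mcmp.T  # (K ref slots, K candidate maps)
    R2 = R**2
    best_perm, best_val = _best_permutation(R2)
    # warn on ambiguous second-best within 1e-9
    second = -np.inf
    for perm in itertools.permutations(range(ts.K)):
        if perm == best_perm:
            continue
        val = sum(R2[j, perm[j]] for j in range(ts.K))
        second = max(second, val)
    if second > best_val - 1e-9:
        warnings.warn("ambiguous template matching; lexicographic tie-break applied")
    signs = np.sign(R[np.arange(ts.K), list(best_perm)])
    signs[signs == 0] = 1
    sorted_maps = ts.maps[list(best_perm)] * signs[:, None]
    return TemplateSet(sorted_maps, ts.montage, reference.labels, level=ts.level, gev=ts.gev)


# ---------------------------------------------------------------------------
# serialization (CSV matrix + JSON sidecar)
# ---------------------------------------------------------------------------

def save_template_set(ts: TemplateSet, prefix: str | Path) -> None:
    """Write ``<prefix>.csv`` (channels x K matrix) and ``<prefix>.json``."""
    prefix = Path(prefix)
    header = ",".join(ts.labels)
    np.savetxt(prefix.with_suffix(".csv"), ts.maps.T, delimiter=",", header=header, comments="")
    meta = {
        "labels": list(ts.labels),
        "level": ts.level,
        "gev": ts.gev,
        "channel_names": list(ts.montage.channel_names),
        "positions": ts.montage.positions.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_template_set(prefix: str | Path) -> TemplateSet:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    maps = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1, ndmin=2).T
    montage = Montage(tuple(meta["channel_names"]), np.asarray(meta["positions"]))
    return TemplateSet(maps, montage, tuple(meta["labels"]), level=meta["level"], gev=meta["gev"])
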