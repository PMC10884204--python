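"""Core data model: montages, scalp topographies, recordings, GFP.

A *topography* (map) is the vector of instantaneous average-referenced scalp
potentials across all electrodes.  Global field power (GFP) is the spatial
standard deviation of that vector around zero; moments of high GFP carry the
best signal-to-noise ratio and are where microstate maps are sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidDataError, MontageError, UndefinedStatisticError

__all__ = [
    "Montage",
    "Topography",
    "Recording",
    "load_sfp",
    "average_reference",
    "global_field_power",
    "spatial_correlation",
    "gfp_curve",
    "find_gfp_peaks",
]


@dataclass(frozen=True)
class Montage:
    """Electrode names and unit-sphere 3D positions.

    Parameters
    ----------
    channel_names
        Unique electrode labels (at least 3).
    positions
        ``(n_channels, 3)`` array of unit-norm coordinates (dimensionless,
        idealized spherical head model).
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self):
        names = tuple(str(n) for n in self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise MontageError(f"positions must be (n, 3), got {pos.shape}")
        if len(names) != pos.shape[0]:
            raise MontageError("channel_names and positions length mismatch")
        if len(names) < 3:
            raise MontageError("a montage needs at least 3 channels")
        if len(set(names)) != len(names):
            raise MontageError("channel names must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.all(np.isfinite(pos)) or np.any(np.abs(norms - 1.0) > 1e-6):
            raise MontageError("positions must lie on the unit sphere (|p| = 1 within 1e-6)")
        pos = pos.copy()
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Montage)
            and self.channel_names == other.channel_names
            and np.allclose(self.positions, other.positions, atol=1e-9)
        )

    def __hash__(self):
        return hash(self.channel_names)


@dataclass(frozen=True)
class Topography:
    """One scalp potential map over a montage (µV, arbitrary scale)."""

    values: np.ndarray
    montage: Montage

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidDataError("topography values must be 1-D")
        if v.shape[0] != self.montage.n_channels:
            raise InvalidDataError(
                f"topography has {v.shape[0]} values for a "
                f"{self.montage.n_channels}-channel montage"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidDataError("topography contains non-finite values")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class Recording:
    """Channels x samples EEG with sampling rate and identity metadata.

    The package consumes *clean* EEG (filtering, artifact rejection and ICA
    happen upstream); the only invariants enforced are structural.
    """

    data: np.ndarray
    srate: float
    montage: Montage
    subject_id: str = "S0"
    session_id: str = "pre"
    day_id: str = "one"

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise InvalidDataError("recording data must be 2-D (channels x samples)")
        if d.shape[0] != self.montage.n_channels:
            raise InvalidDataError("recording rows must match montage channels")
        if d.shape[1] < 2:
            raise InvalidDataError("recording needs at least 2 samples")
        if not np.all(np.isfinite(d)):
            raise InvalidDataError("recording contains non-finite values")
        if not (np.isfinite(self.srate) and self.srate > 0):
            raise InvalidDataError("sampling rate must be positive")
        d = d.copy()
        d.setflags(write=False)
        object.__setattr__(self, "data", d)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate


def load_sfp(path: str | Path) -> Montage:
    """Read a BESA-style ``.sfp`` file (``name x y z`` per line).

    Positions are normalized to the unit sphere; blank lines and ``#``
    comments are ignored.
    """
    names, pos = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise MontageError(f"malformed .sfp line: {line!r}")
        names.append(parts[0])
        pos.append([float(x) for x in parts[1:]])
    pos = np.asarray(pos, dtype=float)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise MontageError("zero-length electrode position")
    return Montage(tuple(names), pos / norms)


# ---------------------------------------------------------------------------
# map-level operations
# ---------------------------------------------------------------------------

def _ref(values: np.ndarray) -> np.ndarray:
    """Average-reference along the channel axis (first axis or 1-D)."""
    return values - values.mean(axis=0, keepdims=values.ndim > 1)


def average_reference(topo: Topography) -> Topography:
    """Re-reference a map to the common average (channel mean becomes 0)."""
    return Topography(_ref(topo.values), topo.montage)


def global_field_power(topo: Topography) -> float:
    """GFP: root-mean-square of the average-referenced map.

    Equals the population standard deviation of the channel values, i.e. the
    "standard deviation of all channels from zero" after average referencing.
    """
    if topo.montage.n_channels < 2:
        raise MontageError("GFP needs at least 2 channels")
    v = _ref(topo.values)
    return float(np.sqrt(np.mean(v**2)))


def spatial_correlation(a: Topography, b: Topography, polarity_invariant: bool = False) -> float:
    """Pearson correlation between two average-referenced maps.

    With ``polarity_invariant=True`` the absolute value is returned, matching
    the microstate convention that a map and its sign-flip are the same state.
    """
    if a.montage != b.montage:
        raise MontageError("spatial correlation requires a common montage")
    va, vb = _ref(a.values), _ref(b.values)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise UndefinedStatisticError("correlation undefined for a zero-variance map")
    r = float(np.dot(va, vb) / (na * nb))
    r = max(-1.0, min(1.0, r))
    return abs(r) if polarity_invariant else r


def gfp_curve(rec: Recording) -> np.ndarray:
    """Per-sample GFP series of a recording (vectorized over samples)."""
    d = _ref(rec.data)
    return np.sqrt(np.mean(d**2, axis=0))


def find_gfp_peaks(
    gfp: Sequence[float] | np.ndarray,
    min_distance_ms: float = 0.0,
    srate: float | None = None,
) -> np.ndarray:
    """Indices of local GFP maxima (strictly above both neighbors).

    Endpoints are excluded.  On a flat run the first sample of the run is the
    candidate peak.  If ``min_distance_ms > 0`` (requires ``srate``), peaks
    closer than that are thinned keeping the higher one.
    """
    g = np.asarray(gfp, dtype=float)
    if g.ndim != 1 or g.size < 3:
        raise InvalidDataError("GFP series must be 1-D with length >= 3")
    # plateau-aware: compare with previous *different* value on the left,
    # and strictly greater than the next value on the right of the run start
    peaks = []
    i = 1
    n = g.size
    while i < n - 1:
        j = i
        while j < n - 1 and g[j + 1] == g[i]:
            j += 1
        # run g[i..j]; peak candidate at i (first sample of flat run)
        if g[i] > g[i - 1] and j < n - 1 and g[i] > g[j + 1]:
            peaks.append(i)
        i = j + 1
    peaks = np.asarray(peaks, dtype=int)
    if min_distance_ms > 0:
        if srate is None:
            raise InvalidDataError("min_distance_ms > 0 requires srate")
        min_gap = min_distance_ms / 1000.0 * srate
        keep: list[int] = []
        for p in peaks[np.argsort(-g[peaks], kind="stable")]:
            if all(abs(p - q) >= min_gap for q in keep):
                keep.append(int(p))
        peaks = np.array(sorted(keep), dtype=int)
    return peaks
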