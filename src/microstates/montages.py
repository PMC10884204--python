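"""Idealized electrode montages on the unit sphere.

``standard_1020_montage`` constructs a 30-channel extended 10-20 layout from
the arc geometry of the system: midline electrodes at fixed fractions of the
nasion-inion arc, the 10% ring at 72 deg inclination from the vertex, lateral
C-line sites on the coronal arc, and intermediate (10-10) sites as normalized
means of their four surrounding electrodes.  The result is an idealized
spherical head model, adequate for spherical-spline work and simulation; it
is not a digitized cap.

Axes: x = right, y = anterior (nose), z = up; head = unit sphere.
"""

from __future__ import annotations

import numpy as np

from .maps import Montage

__all__ = ["standard_1020_montage", "dense_cap_montage"]


def _ang(alpha_deg: float, azim_deg: float) -> np.ndarray:
    """Point at `alpha` degrees from the vertex, azimuth measured from the
    nose (+y) toward the right ear (+x)."""
    a = np.deg2rad(alpha_deg)
    b = np.deg2rad(azim_deg)
    return np.array([np.sin(a) * np.sin(b), np.sin(a) * np.cos(b), np.cos(a)])


def _nmean(*pts: np.ndarray) -> np.ndarray:
    m = np.mean(pts, axis=0)
    return m / np.linalg.norm(m)


def standard_1020_montage() -> Montage:
    """Idealized 30-channel extended 10-20 montage (unit sphere)."""
    p: dict[str, np.ndarray] = {}
    # midline: Fpz at 10% of the nasion-inion arc, Fz 30%, Cz 50%, Pz 70%, Oz 90%
    p["Fz"] = _ang(36, 0)
    p["Cz"] = _ang(0, 0)
    p["Pz"] = _ang(36, 180)
    fpz = _ang(72, 0)
    oz = _ang(72, 180)
    p["Oz"] = oz
    # 10% ring (inclination 72 deg): azimuth from nose, left negative
    ring = {"Fp1": -18, "Fp2": 18, "F7": -54, "F8": 54, "T7": -90, "T8": 90,
            "P7": -126, "P8": 126, "O1": -162, "O2": 162}
    for name, az in ring.items():
        p[name] = _ang(72, az)
    # C-line: halfway between vertex and ears
    p["C3"] = _ang(36, -90)
    p["C4"] = _ang(36, 90)
    # F/P interior sites: midpoint of the arc between the midline and the ring
    p["F3"] = _nmean(p["Fz"], p["F7"])
    p["F4"] = _nmean(p["Fz"], p["F8"])
    p["P3"] = _nmean(p["Pz"], p["P7"])
    p["P4"] = _nmean(p["Pz"], p["P8"])
    # 10-10 rows as normalized means of the four neighbors
    p["FC1"] = _nmean(p["F3"], p["Fz"], p["C3"], p["Cz"])
    p["FC2"] = _nmean(p["F4"], p["Fz"], p["C4"], p["Cz"])
    p["FC5"] = _nmean(p["F7"], p["F3"], p["T7"], p["C3"])
    p["FC6"] = _nmean(p["F8"], p["F4"], p["T8"], p["C4"])
    p["CP1"] = _nmean(p["C3"], p["Cz"], p["P3"], p["Pz"])
    p["CP2"] = _nmean(p["C4"], p["Cz"], p["P4"], p["Pz"])
    p["CP5"] = _nmean(p["T7"], p["C3"], p["P7"], p["P3"])
    p["CP6"] = _nmean(p["T8"], p["C4"], p["P8"], p["P4"])
    p["PO3"] = _nmean(p["P3"], p["Pz"], p["O1"], oz)
    p["PO4"] = _nmean(p["P4"], p["Pz"], p["O2"], oz)
    order = ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
             "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
             "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
             "PO3", "PO4", "O1", "Oz", "O2"]
    return Montage(tuple(order), np.array([p[k] for k in order]))


def dense_cap_montage(n_channels: int = 64, max_inclination_deg: float = 100.0) -> Montage:
    """Synthetic dense electrode cap: a Fibonacci spiral over the upper head.

    Used where a higher-density montage than the idealized 10-20 layout is
    needed (e.g. cross-montage resampling); channel names are ``E1..En``.
    """
    i = np.arange(n_channels)
    # spread cos(alpha) uniformly from vertex down to the cap edge
    cmax = np.cos(np.deg2rad(max_inclination_deg))
    z = 1.0 - (1.0 - cmax) * (i + 0.5) / n_channels
    golden = np.pi * (3.0 - np.sqrt(5.0))
    az = golden * i
    r = np.sqrt(1.0 - z**2)
    pos = np.column_stack([r * np.cos(az), r * np.sin(az), z])
    return Montage(tuple(f"E{k + 1}" for k in i), pos)
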