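"""Spherical-spline interpolation of scalp maps between montages.

Implements Perrin-style spherical splines: the map is modeled as a constant
plus a weighted sum of the kernel

    g(x) = (1/4*pi) * sum_{n=1}^{N} (2n+1) / (n (n+1))**m  P_n(x),

with x the cosine of the angle between electrode positions and P_n the
Legendre polynomials.  Spline order m = 4 and N = 50 expansion terms are the
standard choice for EEG; a small ridge term keeps the system well
conditioned.  Used to re-express template maps on a different montage (e.g.
correlating maps across a 64- and a 30-channel cap).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre

from .errors import MontageError, NumericalError
from .maps import Montage, Topography, _ref

__all__ = ["interpolation_matrix", "spherical_spline_resample"]

_DEFAULT_ORDER = 4
_DEFAULT_TERMS = 50
_DEFAULT_REG = 1e-5


def _g(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1)) ** m / (4 * np.pi)
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coef)


def interpolation_matrix(
    source: Montage,
    target: Montage,
    order: int = _DEFAULT_ORDER,
    n_terms: int = _DEFAULT_TERMS,
    reg: float = _DEFAULT_REG,
) -> np.ndarray:
    """Matrix ``A`` such that ``v_target = A @ v_source`` for spline maps.

    Solves the augmented spline system on the source montage with ridge
    regularization ``reg`` on the kernel block, then evaluates at the target
    positions.  Average-referencing of the input is the caller's job.
    """
    ps, pt = source.positions, target.positions
    ns = ps.shape[0]
    if ns < 10:
        raise MontageError("spherical splines need a source montage with >= 10 channels")
    G = _g(ps @ ps.T, order, n_terms) + reg * np.eye(ns)
    S = np.zeros((ns + 1, ns + 1))
    S[:ns, :ns] = G
    S[:ns, ns] = 1.0
    S[ns, :ns] = 1.0
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular spherical-spline system; raise the regularization (reg)"
        ) from exc
    Gt = _g(pt @ ps.T, order, n_terms)
    # weights for [v; 0] -> spline coefficients [c; d]
    A = np.hstack([Gt, np.ones((pt.shape[0], 1))]) @ Sinv[:, :ns]
    return A


def spherical_spline_resample(
    topo: Topography,
    target: Montage,
    order: int = _DEFAULT_ORDER,
    n_terms: int = _DEFAULT_TERMS,
    reg: float = _DEFAULT_REG,
) -> Topography:
    """Estimate an average-referenced map at the positions of ``target``."""
    A = interpolation_matrix(topo.montage, target, order=order, n_terms=n_terms, reg=reg)
    return Topography(_ref(A @ _ref(topo.values)), target)
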