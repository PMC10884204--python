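"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import microstates as ms
from microstates.maps import _ref


@pytest.fixture(scope="session")
def montage30():
    return ms.standard_1020_montage()


@pytest.fixture(scope="session")
def montage64():
    return ms.dense_cap_montage(64)


@pytest.fixture(scope="session")
def montage3():
    """Minimal 3-electrode montage for hand-computable examples."""
    pos = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    return ms.Montage(("E1", "E2", "E3"), pos)


@pytest.fixture(scope="session")
def templates5(montage30):
    return ms.make_templates(montage30, K=5, seed=1)


@pytest.fixture(scope="session")
def templates2(montage30):
    """Two well-separated quasi-dipolar maps."""
    return ms.make_templates(montage30, K=2, min_pairwise_sep=0.9, seed=4)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def partition_gev(X: np.ndarray, assign: np.ndarray, K: int) -> float:
    """GEV of a fixed partition with first-PC cluster templates.

    Straightforward per-definition computation, independent of the
    clustering code paths.
    """
    X = _ref(X.T).T
    norms = np.linalg.norm(X, axis=1)
    gfp = norms / np.sqrt(X.shape[1])
    Xn = X / norms[:, None]
    num = 0.0
    for k in range(K):
        members = X[assign == k]
        if len(members) == 0:
            continue
        vals, vecs = np.linalg.eigh(members.T @ members)
        t = vecs[:, -1]
        r = np.abs(Xn[assign == k] @ t)
        num += np.sum((gfp[assign == k] * r) ** 2)
    return float(num / np.sum(gfp**2))


def brute_force_best_gev(X: np.ndarray, K: int) -> float:
    """Best GEV over every partition of the maps into K non-empty clusters."""
    n = X.shape[0]
    best = -np.inf
    for assign in itertools.product(range(K), repeat=n):
        if len(set(assign)) != K:
            continue
        best = max(best, partition_gev(X, np.asarray(assign), K))
    return best


def dp_min_smoothing(misfit: np.ndarray, penalty: float, half: int) -> float:
    """Exact minimum of the smoothing objective over all label sequences.

    The objective sum_t misfit[t, l_t] - penalty * N_{t, l_t} equals
    sum_t misfit[t, l_t] - 2 * penalty * #{(s, t): s < t, t - s <= half,
    l_s = l_t}, a banded pairwise energy minimized exactly by dynamic
    programming over the last ``half`` labels (equivalent to exhaustive
    enumeration).
    """
    n, K = misfit.shape
    # state: tuple of the previous `half` labels (most recent last)
    states: dict[tuple[int, ...], float] = {(): 0.0}
    for t in range(n):
        new: dict[tuple[int, ...], float] = {}
        for state, cost in states.items():
            for k in range(K):
                c = cost + misfit[t, k] - 2.0 * penalty * sum(1 for s in state if s == k)
                ns = (state + (k,))[-half:] if half > 0 else ()
                if ns not in new or c < new[ns]:
                    new[ns] = c
        states = new
    return min(states.values())
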