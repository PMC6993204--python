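"""Dynamic time warping with a squared-Euclidean local cost.

Classic unconstrained DTW with the symmetric step pattern
(match / insertion / deletion), as used to align force and position
profiles before computing consistency scores.  The accumulated-cost
recursion runs in a numba-compiled kernel; the optimal path is
recovered by backtracking.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


__all__ = ["dtw_path", "dtw_distance", "warp_onto"]


@njit(cache=True)
def _accumulate(cost: np.ndarray) -> np.ndarray:
    n, m = cost.shape
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = cost[i, j] + best
    return acc


def _local_cost(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - y[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _as_profile(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("profiles must be (N>=2,) or (N>=2, d) arrays")
    return x

def dtw_path(x, y) -> tuple[float, np.ndarray, np.ndarray]:
    """Align two profiles; return (total cost, index path into x, into y).

    The cost is the sum of squared Euclidean distances over the optimal
    monotone alignment path (both endpoints matched).
    """
    x, y = _as_profile(x), _as_profile(y)
    if x.shape[1] != y.shape[1]:
        raise ValueError("profiles must share dimensionality")
    acc = _accumulate(_local_cost(x, y))
    i, j = acc.shape[0] - 1, acc.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            moves = (acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1])
            k = int(np.argmin(moves))
            if k == 0:
                i, j = i - 1, j - 1
            elif k == 1:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    pi = np.array([p[0] for p in path])
    pj = np.array([p[1] for p in path])
    return float(acc[-1, -1]), pi, pj


def dtw_distance(x, y) -> float:
    """Total squared-Euclidean cost of the optimal DTW alignment."""
    x, y = _as_profile(x), _as_profile(y)
    if x.shape[1] != y.shape[1]:
        raise ValueError("profiles must share dimensionality")
    return float(_accumulate(_local_cost(x, y))[-1, -1])


def warp_onto(profile, reference) -> np.ndarray:
    """Warp ``profile`` onto the time base of ``reference``.

    Each reference sample receives the mean of the profile samples the
    DTW path matches to it, yielding an array with the reference's
    length.  Warping a profile onto itself is the identity.
    """
    profile, reference = _as_profile(profile), _as_profile(reference)
    _, pi, pj = dtw_path(profile, reference)
    out = np.zeros((reference.shape[0], profile.shape[1]))
    counts = np.zeros(reference.shape[0])
    np.add.at(out, pj, profile[pi])
    np.add.at(counts, pj, 1.0)
    return out / counts[:, None]
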