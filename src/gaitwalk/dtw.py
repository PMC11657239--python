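"""Dynamic time warping between scalar gait-cycle series.

The DTW dissimilarity between two series ``a`` (length n) and ``b``
(length m) is the minimum, over all warping paths, of the summed local
cost along the path.  A warping path is a sequence of index pairs that
starts at ``(0, 0)``, ends at ``(n-1, m-1)``, and advances by steps from
``{(1, 0), (0, 1), (1, 1)}`` (monotone and continuous).  The local cost
is ``|a_i - b_j|`` by default, keeping the distance in signal units; a
squared-difference cost is available.  The accumulated-cost grid is

    D[i, j] = c(i, j) + min(D[i-1, j], D[i, j-1], D[i-1, j-1])

with ``D[0, 0] = c(0, 0)`` and the usual edge initialisations, and the
distance is ``D[n-1, m-1]``.  DTW is symmetric and non-negative but not a
metric (no triangle inequality).

An optional Sakoe-Chiba band restricts the path to ``|i - j| <= r``; it
is off by default because gait cycles are short and the full grid is
cheap.  Distances are not normalised by path length by default (use
:attr:`DtwResult.normalized_distance` for the per-step variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ValidationError

LOCAL_COSTS = ("abs", "squared")


def _as_series(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name}: empty series")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: non-finite values")
    return arr


@dataclass
class DtwResult:
    """Outcome of a DTW alignment.

    Attributes
    ----------
    distance
        Minimum summed local cost over all admissible warping paths.
    path
        The optimal path as ``[(0, 0), ..., (n-1, m-1)]`` index pairs.
        Ties during backtracking prefer diagonal, then vertical
        ``(i-1, j)``, then horizontal ``(i, j-1)`` steps, so the path is
        deterministic.
    cost_matrix
        The accumulated-cost grid ``D`` (n x m); entries outside a
        requested band are ``+inf``.
    """

    distance: float
    path: list[tuple[int, int]]
    cost_matrix: np.ndarray

    @property
    def normalized_distance(self) -> float:
        """Distance divided by the number of path steps."""
        return self.distance / len(self.path)


@njit(cache=True)
def _dist_kernel(a, b, squared):
    # Two-row dynamic program; returns the DTW distance only.
    n = a.size
    m = b.size
    prev = np.empty(m)
    curr = np.empty(m)
    for j in range(m):
        d = a[0] - b[j]
        c = d * d if squared else abs(d)
        prev[j] = c if j == 0 else prev[j - 1] + c
    for i in range(1, n):
        d = a[i] - b[0]
        curr[0] = prev[0] + (d * d if squared else abs(d))
        for j in range(1, m):
            d = a[i] - b[j]
            c = d * d if squared else abs(d)
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = c + best
        prev, curr = curr, prev
    return prev[m - 1]


@njit(cache=True)
def _accumulate_kernel(C, band):
    # Fills the accumulated-cost grid; band < 0 means unconstrained.
    n, m = C.shape
    D = np.full((n, m), np.inf)
    for i in range(n):
        lo = 0 if band < 0 else max(0, i - band)
        hi = m if band < 0 else min(m, i + band + 1)
        for j in range(lo, hi):
            if i == 0 and j == 0:
                D[0, 0] = C[0, 0]
                continue
            best = np.inf
            if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                best = D[i - 1, j - 1]
            if i > 0 and D[i - 1, j] < best:
                best = D[i - 1, j]
            if j > 0 and D[i, j - 1] < best:
                best = D[i, j - 1]
            if np.isfinite(best):
                D[i, j] = C[i, j] + best
    return D


def _local_cost_matrix(a: np.ndarray, b: np.ndarray, local_cost: str) -> np.ndarray:
    if local_cost not in LOCAL_COSTS:
        raise ValidationError(f"unknown local cost {local_cost!r}; expected one of {LOCAL_COSTS}")
    diff = a[:, None] - b[None, :]
    return diff * diff if local_cost == "squared" else np.abs(diff)


def _check_band(n: int, m: int, band_radius: int | None) -> int:
    if band_radius is None:
        return -1
    band = int(band_radius)
    if band < abs(n - m):
        raise ValidationError(
            f"band_radius {band} infeasible for lengths {n} and {m}: need >= {abs(n - m)}"
        )
    return band


def dtw_align(a, b, local_cost: str = "abs", band_radius: int | None = None) -> DtwResult:
    """Full DTW alignment: distance, accumulated-cost grid, optimal path."""
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    band = _check_band(a.size, b.size, band_radius)
    C = _local_cost_matrix(a, b, local_cost)
    D = _accumulate_kernel(C, band)
    path = _backtrack(D)
    return DtwResult(distance=float(D[-1, -1]), path=path, cost_matrix=D)


def _backtrack(D: np.ndarray) -> list[tuple[int, int]]:
    i, j = D.shape[0] - 1, D.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        candidates = []
        if i > 0 and j > 0:
            candidates.append((D[i - 1, j - 1], i - 1, j - 1))
        if i > 0:
            candidates.append((D[i - 1, j], i - 1, j))
        if j > 0:
            candidates.append((D[i, j - 1], i, j - 1))
        best = min(c[0] for c in candidates)
        # first candidate achieving the min wins: diagonal, vertical, horizontal
        for cost, ni, nj in candidates:
            if cost == best:
                i, j = ni, nj
                break
        path.append((i, j))
    path.reverse()
    return path


def dtw_distance(a, b, local_cost: str = "abs", band_radius: int | None = None) -> float:
    """DTW distance only (no path, no grid); the fast route for scoring."""
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    band = _check_band(a.size, b.size, band_radius)
    if band < 0:
        return float(_dist_kernel(a, b, local_cost == "squared"))
    C = _local_cost_matrix(a, b, local_cost)
    return float(_accumulate_kernel(C, band)[-1, -1])


def euclidean_align(a, b, local_cost: str = "abs") -> float:
    """Straight index-to-index distance (the pre-warping comparison).

    Series of unequal length are truncated to the shorter one.  Under a
    matched local cost and equal lengths this is an upper bound on the
    DTW distance, since the diagonal is one admissible path.
    """
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    k = min(a.size, b.size)
    diff = a[:k] - b[:k]
    if local_cost == "squared":
        return float(np.sum(diff * diff))
    if local_cost == "abs":
        return float(np.sum(np.abs(diff)))
    raise ValidationError(f"unknown local cost {local_cost!r}")


def dump_cost_matrix(result: DtwResult, path) -> None:
    """Write the accumulated-cost grid to CSV (row = index in ``a``)."""
    np.savetxt(path, result.cost_matrix, delimiter=",")
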