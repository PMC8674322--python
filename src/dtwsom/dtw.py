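"""Exact and Sakoe-Chiba-constrained dynamic time warping with path extraction.

The DTW distance between two series ``a`` (length n) and ``b`` (length m) is
the minimum, over all admissible warping paths, of the summed local costs
``|a[i] - b[j]|`` along the path.  An admissible path starts at ``(0, 0)``,
ends at ``(n-1, m-1)``, and advances by steps ``(1, 0)``, ``(0, 1)`` or
``(1, 1)`` — the boundary, monotonicity and continuity constraints.  Path cost
is the plain (unnormalised) sum; local cost is the scalar Euclidean distance.

The Sakoe-Chiba band restricts the path to cells with ``|i - j| <= band``,
trading a provably optimal path for a near-diagonal search that is both faster
and, on day-length series whose misalignment is bounded (tens of minutes), an
excellent approximation to the exact distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

__all__ = ["DtwResult", "compute_dtw", "dtw_oracle"]


@dataclass(frozen=True)
class DtwResult:
    """Outcome of a DTW computation.

    Attributes
    ----------
    distance:
        Minimal cumulative cost, ``sum(|a[i] - b[j]|)`` over the path.
    path:
        ``(L, 2)`` integer array of aligned index pairs, in path order,
        from ``(0, 0)`` to ``(n-1, m-1)``.
    """

    distance: float
    path: np.ndarray


@njit(cache=False)
def _dtw_dp(a, b, band):  # pragma: no cover - exercised via compute_dtw
    """Cumulative-cost DP and backtracked optimal path.

    ``band < 0`` means unconstrained.  Backtracking tie-break: prefer the
    diagonal predecessor, then the vertical one — optimal paths are not
    unique, so a deterministic rule is required.
    """
    n = a.shape[0]
    m = b.shape[0]
    INF = np.inf
    D = np.full((n, m), INF)
    for i in range(n):
        if band >= 0:
            j_lo = max(0, i - band)
            j_hi = min(m - 1, i + band)
        else:
            j_lo = 0
            j_hi = m - 1
        for j in range(j_lo, j_hi + 1):
            c = abs(a[i] - b[j])
            if i == 0 and j == 0:
                D[i, j] = c
            else:
                best = INF
                if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                    best = D[i - 1, j - 1]
                if i > 0 and D[i - 1, j] < best:
                    best = D[i - 1, j]
                if j > 0 and D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = c + best

    # backtrack
    path = np.empty((n + m - 1, 2), dtype=np.int64)
    k = n + m - 2
    i = n - 1
    j = m - 1
    path[k, 0] = i
    path[k, 1] = j
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = D[i - 1, j - 1]
            vert = D[i - 1, j]
            horz = D[i, j - 1]
            if diag <= vert and diag <= horz:
                i -= 1
                j -= 1
            elif vert <= horz:
                i -= 1
            else:
                j -= 1
        elif i > 0:
            i -= 1
        else:
            j -= 1
        k -= 1
        path[k, 0] = i
        path[k, 1] = j
    return D[n - 1, m - 1], path[k:]


def compute_dtw(a, b, band: int | None = None) -> DtwResult:
    """Dynamic time warping distance and one optimal warping path.

    Parameters
    ----------
    a, b:
        Non-empty 1-D real sequences; lengths may differ.
    band:
        Sakoe-Chiba half-width: only cells with ``|i - j| <= band`` are
        admissible.  ``None`` (default) searches the full matrix.  Must be
        at least ``|len(a) - len(b)|``, else no admissible path exists.

    Returns
    -------
    DtwResult
        Distance and an ``(L, 2)`` index-pair path.  When several paths are
        optimal the diagonal-preferring backtrack picks one deterministically.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("compute_dtw expects 1-D series")
    if a.size == 0 or b.size == 0:
        raise ValueError("compute_dtw: series must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("compute_dtw: series must be finite (no missing values)")
    if band is not None:
        band = int(band)
        if band < 0:
            raise ValueError("compute_dtw: band must be >= 0 or None")
        if band < abs(a.size - b.size):
            raise ValueError(
                f"compute_dtw: band {band} < length difference "
                f"{abs(a.size - b.size)}; no admissible path"
            )
    dist, path = _dtw_dp(a, b, -1 if band is None else band)
    return DtwResult(distance=float(dist), path=path)


@lru_cache(maxsize=None)
def _all_paths(n: int, m: int) -> tuple[np.ndarray, ...]:
    """Every admissible warping path through an n-by-m grid, as flat indices
    into the row-major local-cost matrix, stacked by path length.  Cached
    per shape so repeated oracle calls pay enumeration once."""
    paths: list[list[int]] = []

    def extend(i: int, j: int, acc: list[int]) -> None:
        acc.append(i * m + j)
        if i == n - 1 and j == m - 1:
            paths.append(list(acc))
        else:
            if i + 1 < n and j + 1 < m:
                extend(i + 1, j + 1, acc)
            if i + 1 < n:
                extend(i + 1, j, acc)
            if j + 1 < m:
                extend(i, j + 1, acc)
        acc.pop()

    extend(0, 0, [])
    by_length: dict[int, list[list[int]]] = {}
    for p in paths:
        by_length.setdefault(len(p), []).append(p)
    return tuple(np.asarray(group, dtype=np.intp)
                 for group in by_length.values())


def dtw_oracle(a, b) -> float:
    """DTW distance by brute-force enumeration of every admissible path.

    Test oracle only: the path count grows combinatorially, so inputs are
    capped at length 8.  Independent of the dynamic program in
    :func:`compute_dtw`.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_oracle: series must be non-empty")
    if a.size > 8 or b.size > 8:
        raise ValueError("dtw_oracle: series longer than 8 (combinatorial blow-up)")
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    return float(min(cost[group].sum(axis=1).min()
                     for group in _all_paths(a.size, b.size)))
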