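"""Pairwise dynamic time warping of genomic signals.

Two preprocessed signals x (length N) and y (length M) are aligned on a
monotone, continuous warping path through an accumulated-distance table

    D(i, j) = min[D(i-1, j-1), D(i-1, j), D(i, j-1)] + d(i, j)

with local cost d(i, j) = |x_i - y_j| (squared cost available as an
option).  Backtracking from (N, M) to (1, 1) picks the minimal predecessor,
breaking ties diagonal > vertical > horizontal.  Warping stretches either
signal by repeating the samples selected by the path; the reported distance
is the Euclidean distance of the warped pair divided by the aligned length,

    distance = sqrt( sum_k (x[i_k] - y[j_k])^2 ) / L ,

so signals of different lengths remain comparable.  A path-cost variant
(D(N, M) / L) is available via ``method="path_cost"``.

DTW is symmetric and satisfies distance(x, x) = 0, but it is not a metric:
the triangle inequality can fail.  It is used here only as a dissimilarity
for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
from numba import njit

from .errors import EmptyInputError, ParameterError
from .signal_transform import GenomicSignal


def _values(signal) -> np.ndarray:
    x = signal.values if isinstance(signal, GenomicSignal) else np.asarray(
        signal, dtype=np.float64
    )
    if x.size == 0:
        raise EmptyInputError("DTW requires non-empty signals")
    return np.ascontiguousarray(x, dtype=np.float64)


@dataclass
class DTWTable:
    """Local-distance matrix d and accumulated-distance matrix D (N x M)."""

    d: np.ndarray
    D: np.ndarray


@dataclass
class DTWResult:
    """Outcome of one pairwise alignment.

    ``path`` is 1-based index pairs from (1, 1) to (N, M); ``warped_x`` and
    ``warped_y`` are the equal-length sample-repeated signals along it.
    ``distance`` is the length-normalized Euclidean distance of the warped
    pair; ``path_cost`` is the accumulated table cost D(N, M).
    """

    path: List[Tuple[int, int]]
    warped_x: np.ndarray
    warped_y: np.ndarray
    distance: float
    path_cost: float

    @property
    def aligned_length(self) -> int:
        return len(self.path)


def local_distances(x, y, squared: bool = False) -> np.ndarray:
    """Pairwise local cost d(i, j) = |x_i - y_j| (or its square)."""
    xv = _values(x)
    yv = _values(y)
    d = np.abs(xv[:, None] - yv[None, :])
    return d * d if squared else d


@njit(cache=False)
def _accumulate_full(d):  # pragma: no cover - exercised via accumulate()
    N, M = d.shape
    D = np.empty((N, M))
    D[0, 0] = d[0, 0]
    for j in range(1, M):
        D[0, j] = D[0, j - 1] + d[0, j]
    for i in range(1, N):
        D[i, 0] = D[i - 1, 0] + d[i, 0]
    for i in range(1, N):
        for j in range(1, M):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = best + d[i, j]
    return D


@njit(cache=False)
def _accumulate_last_rolling(x, y):  # pragma: no cover
    N = x.size
    M = y.size
    prev = np.empty(M)
    cur = np.empty(M)
    prev[0] = abs(x[0] - y[0])
    for j in range(1, M):
        prev[j] = prev[j - 1] + abs(x[0] - y[j])
    for i in range(1, N):
        cur[0] = prev[0] + abs(x[i] - y[0])
        for j in range(1, M):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = best + abs(x[i] - y[j])
        prev, cur = cur, prev
    return prev[M - 1]


def accumulate(d: np.ndarray) -> np.ndarray:
    """Fill the accumulated-distance table from the local-cost matrix."""
    d = np.ascontiguousarray(d, dtype=np.float64)
    if d.size == 0:
        raise EmptyInputError("empty local-distance matrix")
    return _accumulate_full(d)


def path_cost_only(x, y) -> float:
    """D(N, M) via a two-row rolling computation (no table retained).

    Contract: identical to ``accumulate(local_distances(x, y))[-1, -1]``.
    Only supports the absolute-difference local cost.
    """
    return float(_accumulate_last_rolling(_values(x), _values(y)))


def backtrack(D: np.ndarray) -> List[Tuple[int, int]]:
    """Minimal-predecessor path from (N, M) back to (1, 1), forward order.

    Ties are broken preferring the diagonal, then the vertical predecessor.
    Returned indices are 1-based.
    """
    N, M = D.shape
    i, j = N - 1, M - 1
    path = [(i + 1, j + 1)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
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
        path.append((i + 1, j + 1))
    path.reverse()
    return path


def warp(x, y, path: List[Tuple[int, int]], path_cost: float = float("nan")) -> DTWResult:
    """Stretch both signals along the path by repeating selected samples."""
    xv = _values(x)
    yv = _values(y)
    idx = np.asarray(path, dtype=np.int64)
    if idx[0, 0] != 1 or idx[0, 1] != 1 or idx[-1, 0] != xv.size or idx[-1, 1] != yv.size:
        raise ParameterError("warping path does not span the signal pair")
    warped_x = xv[idx[:, 0] - 1]
    warped_y = yv[idx[:, 1] - 1]
    L = len(path)
    distance = float(np.sqrt(np.sum((warped_x - warped_y) ** 2)) / L)
    return DTWResult(
        path=list(path),
        warped_x=warped_x,
        warped_y=warped_y,
        distance=distance,
        path_cost=float(path_cost),
    )


def band_mask(n: int, m: int, band: float) -> np.ndarray:
    """Sakoe-Chiba-style corridor: allowed where the path stays within
    ``band`` (fraction of the unit diagonal) of the rescaled diagonal."""
    if not 0 < band <= 1:
        raise ParameterError("band must be in (0, 1]")
    i = np.arange(n)[:, None] / max(n - 1, 1)
    j = np.arange(m)[None, :] / max(m - 1, 1)
    return np.abs(i - j) <= band


def dtw(x, y, squared_local: bool = False, band: Optional[float] = None) -> DTWResult:
    """Full alignment: local costs -> accumulate -> backtrack -> warp.

    ``band`` optionally restricts the path to a diagonal corridor (fraction
    of the signal length), mainly as a speed/regularity control.
    """
    d = local_distances(x, y, squared=squared_local)
    if band is not None:
        d = np.where(band_mask(*d.shape, band), d, np.inf)
    D = accumulate(d)
    path = backtrack(D)
    return warp(x, y, path, path_cost=D[-1, -1])


def dtw_distance(x, y, method: str = "warped_euclidean", band: Optional[float] = None) -> float:
    """Length-normalized DTW distance between two signals.

    ``method="warped_euclidean"`` (default): Euclidean distance of the
    sample-repeated pair divided by the aligned length.
    ``method="path_cost"``: accumulated table cost D(N, M) divided by the
    aligned length.  The path-cost form is monotonically faithful to signal
    divergence (the warped-pair form can shrink under heavy warping) and is
    the default for distance-matrix construction in :mod:`phasewarp.cluster`.
    """
    result = dtw(x, y, band=band)
    if method == "warped_euclidean":
        return result.distance
    if method == "path_cost":
        return result.path_cost / result.aligned_length
    raise ParameterError(f"unknown DTW distance method {method!r}")


def write_path(path: List[Tuple[int, int]], out: Union[str, Path]) -> None:
    """Export a warping path as two-column (i, j) plain text, 1-based."""
    with open(out, "w") as handle:
        for i, j in path:
            handle.write(f"{i}\t{j}\n")


def write_aligned_pair(result: DTWResult, out: Union[str, Path]) -> None:
    """Export the warped pair as three-column text: step, x, y."""
    with open(out, "w") as handle:
        handle.write(f"# aligned_length={result.aligned_length} "
                     f"distance={result.distance:.12g}\n")
        for k, (a, b) in enumerate(zip(result.warped_x, result.warped_y), 1):
            handle.write(f"{k}\t{a:.12g}\t{b:.12g}\n")
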