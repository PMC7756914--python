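"""Dynamic time warping of equal-length symptom-score series.

The alignment uses the symmetric Sakoe-Chiba step pattern with slope
constraint P = 0 ("symmetricP0"): a diagonal move costs twice the local
distance, horizontal and vertical moves cost it once, and the warping path
is confined to the band |i - j| <= w.  Both endpoints are anchored (global
alignment).  The local cost is the absolute score difference.

Conventions
-----------
* The first cell is treated as a diagonal entry step, g(1,1) = 2*|x_1 - y_1|,
  so a forced-diagonal alignment (w = 0) accumulates sum_i 2*|x_i - y_i|.
* The reported ``distance`` is the unnormalized accumulated cost; the
  normalized distance d / (N + M) is always computed alongside.
* Backtracking prefers diagonal, then vertical, then horizontal moves, which
  makes the recovered path (not the distance) deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DTWParams", "AlignmentResult", "dtw_align", "brute_force_align", "pairwise_dtw"]

_DIAG_WEIGHT = 2.0  # diagonal step weight of the symmetricP0 pattern
_SIDE_WEIGHT = 1.0  # horizontal / vertical step weight


@dataclass(frozen=True)
class DTWParams:
    """Alignment settings.

    band_width : int or None
        Sakoe-Chiba band half-width w (|i - j| <= w); ``None`` disables the
        constraint.  The default of 2 matches scores up to +/- two visits
        (+/- 4 weeks at a biweekly schedule).
    step_pattern : str
        Only ``"symmetric_p0"`` is supported.
    normalized : bool
        If True, distance matrices built with these parameters hold the
        length-normalized d / (N + M) instead of the raw accumulated cost
        (:class:`AlignmentResult` always carries both).
    """

    band_width: int | None = 2
    step_pattern: str = "symmetric_p0"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.band_width is not None and self.band_width < 0:
            raise ValueError("band_width must be >= 0 (or None for unconstrained)")
        if self.step_pattern != "symmetric_p0":
            raise ValueError(f"unsupported step pattern: {self.step_pattern!r}")


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one pairwise alignment.

    ``path`` is the optimal warping path as 1-based (i, j) index pairs from
    (1, 1) to (N, M).
    """

    distance: float
    normalized_distance: float
    path: tuple[tuple[int, int], ...] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "distance": self.distance,
            "normalized_distance": self.normalized_distance,
            "path": [list(p) for p in self.path],
        }


def _as_values(series) -> np.ndarray:
    values = np.asarray(getattr(series, "values", series), dtype=float)
    if values.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if values.size < 2:
        raise ValueError("series must have at least 2 time points")
    return values


def _check_lengths(x: np.ndarray, y: np.ndarray) -> None:
    if x.size != y.size:
        raise ValueError(
            f"series lengths differ ({x.size} vs {y.size}); items within one "
            "patient always share visits, so only equal lengths are supported"
        )


def dtw_align(x, y, params: DTWParams = DTWParams()) -> AlignmentResult:
    """Align two equal-length series and return the banded DTW distance.

    Solves the recurrence
    ``g(i,j) = min(g(i-1,j-1) + 2 c(i,j), g(i-1,j) + c(i,j), g(i,j-1) + c(i,j))``
    with ``c(i,j) = |x_i - y_j|`` over the band ``|i - j| <= w``, anchored at
    both endpoints.
    """
    xv, yv = _as_values(x), _as_values(y)
    _check_lengths(xv, yv)
    n = xv.size
    w = n if params.band_width is None else int(params.band_width)

    cost = np.abs(xv[:, None] - yv[None, :])
    g = np.full((n, n), np.inf)
    g[0, 0] = _DIAG_WEIGHT * cost[0, 0]
    for i in range(n):
        j_lo, j_hi = max(0, i - w), min(n - 1, i + w)
        for j in range(j_lo, j_hi + 1):
            if i == 0 and j == 0:
                continue
            c = cost[i, j]
            best = np.inf
            if i > 0 and j > 0:
                best = g[i - 1, j - 1] + _DIAG_WEIGHT * c
            if i > 0:
                best = min(best, g[i - 1, j] + _SIDE_WEIGHT * c)
            if j > 0:
                best = min(best, g[i, j - 1] + _SIDE_WEIGHT * c)
            g[i, j] = best

    d = float(g[n - 1, n - 1])
    if not np.isfinite(d):  # cannot happen for equal lengths and w >= 0
        raise ValueError("no feasible warping path inside the band")

    # Backtrack one argmin path; ties broken diagonal > vertical > horizontal.
    path = [(n, n)]
    i = j = n - 1
    while i > 0 or j > 0:
        c = cost[i, j]
        candidates = []  # in preference order: diagonal, vertical, horizontal
        if i > 0 and j > 0:
            candidates.append((g[i - 1, j - 1] + _DIAG_WEIGHT * c, i - 1, j - 1))
        if i > 0:
            candidates.append((g[i - 1, j] + _SIDE_WEIGHT * c, i - 1, j))
        if j > 0:
            candidates.append((g[i, j - 1] + _SIDE_WEIGHT * c, i, j - 1))
        target = g[i, j]
        for value, pi, pj in candidates:
            if np.isclose(value, target):
                i, j = pi, pj
                break
        else:  # numerical safety net: take the smallest predecessor value
            _, i, j = min(candidates)
        path.append((i + 1, j + 1))
    path.reverse()

    return AlignmentResult(
        distance=d,
        normalized_distance=d / (2 * n),
        path=tuple(path),
    )


def brute_force_align(x, y, params: DTWParams = DTWParams()) -> AlignmentResult:
    """Exhaustive-enumeration oracle for :func:`dtw_align`.

    Enumerates every anchored monotone warping path inside the band and
    costs each with the same step weights (entry and diagonal steps weighted
    2, horizontal/vertical steps weighted 1).  Intended for small inputs
    (len(x) * len(y) <= 64); independent of the dynamic-programming route.
    """
    xv, yv = _as_values(x), _as_values(y)
    _check_lengths(xv, yv)
    n = xv.size
    if n * n > 64:
        raise ValueError("series too long for exhaustive enumeration")
    w = n if params.band_width is None else int(params.band_width)
    cost = np.abs(xv[:, None] - yv[None, :])

    best: list = [np.inf, None]

    def extend(i: int, j: int, acc: float, path: list) -> None:
        if acc >= best[0]:
            return
        if i == n - 1 and j == n - 1:
            best[0], best[1] = acc, list(path)
            return
        for di, dj, weight in ((1, 1, _DIAG_WEIGHT), (1, 0, _SIDE_WEIGHT), (0, 1, _SIDE_WEIGHT)):
            ni, nj = i + di, j + dj
            if ni >= n or nj >= n or abs(ni - nj) > w:
                continue
            path.append((ni + 1, nj + 1))
            extend(ni, nj, acc + weight * cost[ni, nj], path)
            path.pop()

    extend(0, 0, _DIAG_WEIGHT * cost[0, 0], [(1, 1)])
    d = float(best[0])
    return AlignmentResult(distance=d, normalized_distance=d / (2 * n), path=tuple(best[1]))


def pairwise_dtw(columns: np.ndarray, params: DTWParams = DTWParams()) -> np.ndarray:
    """All-pairs banded DTW distances between the columns of a T x K matrix.

    Vectorizes the dynamic program across every ordered column pair at once,
    which keeps whole-cohort runs (hundreds of patients x 136 item pairs)
    fast without changing the arithmetic of :func:`dtw_align`.

    Returns the symmetric K x K matrix of accumulated costs (zero diagonal).
    """
    X = np.asarray(columns, dtype=float)
    if X.ndim != 2:
        raise ValueError("columns must be a T x K matrix")
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least 2 visits")
    w = n if params.band_width is None else int(params.band_width)

    # cost[i, j] is the K x K matrix |X[i, a] - X[j, b]| over column pairs.
    cost = np.abs(X[:, None, :, None] - X[None, :, None, :])
    g = np.full((n, n, k, k), np.inf)
    g[0, 0] = _DIAG_WEIGHT * cost[0, 0]
    inf = np.full((k, k), np.inf)
    for i in range(n):
        j_lo, j_hi = max(0, i - w), min(n - 1, i + w)
        for j in range(j_lo, j_hi + 1):
            if i == 0 and j == 0:
                continue
            c = cost[i, j]
            best = inf
            if i > 0 and j > 0:
                best = g[i - 1, j - 1] + _DIAG_WEIGHT * c
            if i > 0:
                best = np.minimum(best, g[i - 1, j] + _SIDE_WEIGHT * c)
            if j > 0:
                best = np.minimum(best, g[i, j - 1] + _SIDE_WEIGHT * c)
            g[i, j] = best

    out = g[n - 1, n - 1]
    out = 0.5 * (out + out.T)  # symmetric up to float noise; make it exact
    np.fill_diagonal(out, 0.0)
    return out
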