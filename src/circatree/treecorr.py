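"""Auto- and cross-correlation for tree-structured lineage data.

Lineages extracted from a division tree duplicate their shared ancestral
segments, so naively averaging per-lineage correlations over-weights early
data.  The tree-corrected estimator subtracts, for every pair of consecutive
lineages in depth-first order, the lagged products that fall entirely inside
their shared prefix, so each distinct data pair is weighed exactly once:

    S_xy(tau) = [ sum_i sum_n x_i(n+tau) y_i(n)
                  - sum_i sum_{n < d_i - tau} x_i(n+tau) y_i(n) ] / D(tau)

with d_i the index where lineages i and i+1 diverge, series centred
beforehand, and the negative branch S_xy(-tau) = S_yx(tau).  The default
denominator D(tau) = Nc (Nt-tau) - sum_i max(d_i - tau, 0) is the number of
*distinct* pairs, matching the corrected numerator; dividing instead by the
duplicate-inclusive count Nc (Nt-tau) (normalisation="counts") makes the
estimate depend on how strongly each lag window overlaps shared ancestry --
in a colony grown from one founder that distorts R increasingly with lag.
The normalisation R = S_xy(tau) / sqrt(S_xx(0) S_yy(0)) uses the same estimator at lag zero,
so R_xx(0) = 1 and prefactors cancel; the estimate is invariant under
duplicating a lineage.

Sign convention: with x leading (y(n) = x(n-d), y lagging x by d), the peak
of R_xy appears at lag -d.  The divergence d_i is measured as the longest
common prefix of the two lineages' data; for measured (noisy) data this is
the division frame, and it extends naturally through literally repeated
data so that duplicates are fully discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peaks import detect_peaks

__all__ = [
    "CorrelationResult",
    "standard_xcorr",
    "tree_xcorr",
    "average_movies",
    "correlation_peaks",
]


class CorrelationError(ValueError):
    pass


@dataclass
class CorrelationResult:
    """Normalised correlation R over a symmetric lag grid (hours)."""

    lags: np.ndarray
    R: np.ndarray
    n_movies: int = 1
    sem: np.ndarray | None = None
    per_movie: np.ndarray | None = None  # (n_movies, n_lags)

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


def _check_lags(dt: float, lag_max_h: float) -> int:
    L = int(np.floor(lag_max_h / dt + 1e-9))
    if L < 1:
        raise CorrelationError("lag_max_h smaller than the sampling interval")
    return L


def standard_xcorr(
    x: np.ndarray,
    y: np.ndarray,
    dt: float = 0.75,
    lag_max_h: float = 48.0,
) -> CorrelationResult:
    """Normalised cross-correlation of two equal-length series.

    S_xy(tau) = 1/(Nt - tau) * sum_n x~(n+tau) y~(n) for tau >= 0 frames,
    S_xy(-tau) = S_yx(tau), with x~, y~ the series minus their means;
    R = S / sqrt(S_xx(0) S_yy(0)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("series must be equal-length 1-D arrays")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("constant series: correlation undefined")
    L = _check_lags(dt, lag_max_h)
    if L >= len(x):
        raise CorrelationError("lag_max_h exceeds the series span")
    xt = x - x.mean()
    yt = y - y.mean()

    def s(a, b, tau):  # tau >= 0 in frames: a(n+tau) b(n)
        n = len(a) - tau
        return float(np.dot(a[tau:], b[:n])) / n

    sxx0 = s(xt, xt, 0)
    syy0 = s(yt, yt, 0)
    lags = dt * np.arange(-L, L + 1)
    R = np.empty(len(lags))
    for k, tau in enumerate(range(-L, L + 1)):
        v = s(xt, yt, tau) if tau >= 0 else s(yt, xt, -tau)
        R[k] = v / np.sqrt(sxx0 * syy0)
    return CorrelationResult(lags=lags, R=R)


def _divergences(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Longest common data prefix of consecutive lineage rows."""
    nc, nt = X.shape
    d = np.empty(nc - 1, dtype=int)
    for i in range(nc - 1):
        same = (X[i] == X[i + 1]) & (Y[i] == Y[i + 1])
        bad = np.nonzero(~same)[0]
        d[i] = nt if bad.size == 0 else int(bad[0])
    return d


def tree_xcorr(
    X: np.ndarray,
    Y: np.ndarray,
    dt: float = 0.75,
    lag_max_h: float = 48.0,
    centring: str = "lineage",
    normalisation: str = "pairs",
) -> CorrelationResult:
    """Tree-corrected cross-correlation over lineage matrices.

    ``X``/``Y`` hold one row per depth-first lineage on the movie's common
    frame grid.  ``centring`` is "lineage" (each row minus its own mean, the
    default; it makes the estimator exactly reduce to the standard one for a
    single or duplicated lineage) or "movie" (rows minus the frame-wise
    across-lineage mean, which isolates fluctuations around the colony
    average).  ``normalisation`` is "pairs" (divide by the distinct-pair
    count, default) or "counts" (divide by Nc*(Nt-tau)).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape != Y.shape:
        raise CorrelationError("lineage matrices must share one frame grid")
    nc, nt = X.shape
    L = _check_lags(dt, lag_max_h)
    if L >= nt:
        raise CorrelationError("lag_max_h exceeds the movie span")
    if centring == "lineage":
        Xt = X - X.mean(axis=1, keepdims=True)
        Yt = Y - Y.mean(axis=1, keepdims=True)
    elif centring == "movie":
        Xt = X - X.mean(axis=0, keepdims=True)
        Yt = Y - Y.mean(axis=0, keepdims=True)
    else:
        raise CorrelationError("centring must be 'lineage' or 'movie'")
    if normalisation not in ("pairs", "counts"):
        raise CorrelationError("normalisation must be 'pairs' or 'counts'")
    d = _divergences(X, Y) if nc > 1 else np.empty(0, dtype=int)

    def s(A, B, tau):  # tau >= 0 frames, correction on shared prefixes
        n = nt - tau
        total = float(np.einsum("ij,ij->", A[:, tau:], B[:, :n]))
        denom = n * nc
        for i, di in enumerate(d):
            m = di - tau
            if m > 0:
                total -= float(np.dot(A[i, tau : tau + m], B[i, :m]))
                if normalisation == "pairs":
                    denom -= m
        return total / denom

    sxx0 = s(Xt, Xt, 0)
    syy0 = s(Yt, Yt, 0)
    if sxx0 <= 0 or syy0 <= 0:
        raise CorrelationError("degenerate (constant) lineage data")
    lags = dt * np.arange(-L, L + 1)
    R = np.empty(len(lags))
    for k, tau in enumerate(range(-L, L + 1)):
        v = s(Xt, Yt, tau) if tau >= 0 else s(Yt, Xt, -tau)
        R[k] = v / np.sqrt(sxx0 * syy0)
    return CorrelationResult(lags=lags, R=R)


def average_movies(results: list[CorrelationResult]) -> CorrelationResult:
    """Unweighted mean across movies plus the across-movie standard error."""
    if not results:
        raise CorrelationError("no movies to average")
    lags = results[0].lags
    for r in results[1:]:
        if len(r.lags) != len(lags) or not np.allclose(r.lags, lags):
            raise CorrelationError("movies have mismatched lag grids")
    stack = np.vstack([r.R for r in results])
    m = len(results)
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(m) if m > 1 else np.zeros_like(mean)
    return CorrelationResult(lags=lags, R=mean, n_movies=m, sem=sem, per_movie=stack)


def correlation_peaks(
    result: CorrelationResult,
    exclude_zero: bool = True,
    min_separation_h: float = 3.0,
) -> np.ndarray:
    """Sorted |lag| values of the local maxima of R.

    Maxima are found with the same detector as expression peaks (3-h
    separation, 2-h minimum FWHM), optionally excluding the trivial lag-zero
    maximum of an auto-correlation.
    """
    ps = detect_peaks(result.lags, result.R, min_separation_h=min_separation_h)
    lags = np.array([p.time_h for p in ps])
    if exclude_zero:
        lags = lags[np.abs(lags) > result.dt / 2.0]
    return np.sort(np.abs(lags))
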