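"""Single-cell elongation and expression rates.

Cell length in rod-shaped cells is a good volume proxy, so the instantaneous
elongation rate -- the exponent of a local exponential fit to length vs time
-- stands in for single-cell growth rate.  Division halves the length, so
before fitting, a lineage's log-length series is *stitched*: at every
division the daughter segment is rescaled (a constant offset in log space)
so the profile continues the mother's local slope, yielding a continuous,
monotonic log-length profile that windows can straddle.  The window width is
one-third of the colony's mean completed cell-cycle time.

Expression rate is the centered finite difference of the smoothed reporter
signal (one-sided at the series ends).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lineages import MovieTable
from .traces import Trace, extract_lineages, smooth_segment

__all__ = [
    "RateSeries",
    "stitch_lengths",
    "elongation_rate",
    "expression_rate",
    "mean_cycle_time",
    "movie_rate_traces",
    "movie_rate_table",
    "colony_mean_rates",
]


class StitchError(ValueError):
    pass


@dataclass
class RateSeries:
    """Per-frame rates along one lineage (1/h for elongation, a.u./h for
    expression)."""

    lineage_id: str
    times: np.ndarray
    rate: np.ndarray
    segment_ids: np.ndarray


def stitch_lengths(trace: Trace) -> np.ndarray:
    """Continuous log-length series for one lineage.

    At each division (segment boundary) the jump between the mother's last
    log-length and the daughter's first is removed after accounting for one
    sampling interval of growth, estimated from the local slope on the
    mother's side (the daughter's side for a one-frame mother).  For
    noiseless exponential growth the result is exactly linear through
    divisions; an exact f / (1-f) split is undone exactly.
    """
    v = np.asarray(trace.values, dtype=float)
    if np.any(v <= 0):
        raise StitchError(f"non-positive length in lineage {trace.lineage_id}")
    logl = np.log(v)
    seg = trace.segment_ids
    t = trace.times
    out = logl.copy()
    offset = 0.0
    boundaries = np.nonzero(seg[1:] != seg[:-1])[0] + 1
    for b in boundaries:
        if b < 2:
            if b + 1 >= len(logl):
                raise StitchError(
                    f"too few frames around division of cell {seg[b - 1]}"
                )
            slope = (logl[b + 1] - logl[b]) / (t[b + 1] - t[b])
        else:
            slope = (logl[b - 1] - logl[b - 2]) / (t[b - 1] - t[b - 2])
        predicted = logl[b - 1] + slope * (t[b] - t[b - 1])
        offset += logl[b] - predicted
        out[b:] = logl[b:] - offset
    return out


def _window_slopes(t: np.ndarray, y: np.ndarray, half: int) -> np.ndarray:
    """OLS slope of y vs t in a centered window of 2*half+1 samples,
    shrinking (minimum 3 points) at the series ends."""
    n = len(t)
    slopes = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        if hi - lo < 3:  # shrink but keep at least 3 points
            lo, hi = max(0, min(lo, n - 3)), min(n, max(hi, 3))
        tt = t[lo:hi]
        yy = y[lo:hi]
        tm = tt.mean()
        slopes[i] = np.dot(tt - tm, yy - yy.mean()) / np.dot(tt - tm, tt - tm)
    return slopes


def mean_cycle_time(table: MovieTable) -> float:
    """Mean completed (division-to-division) cycle time of the colony."""
    cycles = table.completed_cycle_times()
    if cycles.size == 0:
        raise ValueError("no completed cell cycles in movie")
    return float(cycles.mean())


def elongation_rate(
    trace: Trace,
    window_h: float | None = None,
    smooth: bool = True,
) -> RateSeries:
    """Windowed exponential-fit elongation rate along one length lineage.

    The log-length series is stitched across divisions, optionally smoothed
    with the 5-point moving average (shrinking at the ends; linear profiles
    pass through unchanged), then the rate at each frame is the least-squares
    slope of log-length over the centered window.  Exact for noiseless
    exponential growth.
    """
    if window_h is None:
        raise ValueError("window_h is required (one-third of the mean cycle time)")
    dt = trace.dt
    half = max(1, int(round(window_h / dt)) // 2)
    if len(trace) < 3:
        raise ValueError("lineage shorter than the minimum 3-point window")
    logl = stitch_lengths(trace)
    if smooth:
        logl = smooth_segment(logl)
    slopes = _window_slopes(trace.times, logl, half)
    return RateSeries(trace.lineage_id, trace.times, slopes, trace.segment_ids)


def expression_rate(trace: Trace) -> RateSeries:
    """Centered finite-difference derivative of the (smoothed) reporter
    signal; one-sided at the ends.  A linear ramp returns its slope
    everywhere."""
    if len(trace) < 3:
        raise ValueError("expression rate needs at least 3 points")
    rate = np.gradient(trace.values, trace.times)
    return RateSeries(trace.lineage_id, trace.times, rate, trace.segment_ids)


def movie_rate_traces(
    table: MovieTable,
    window_h: float | None = None,
    smoothed_table: MovieTable | None = None,
) -> tuple[list[RateSeries], list[RateSeries]]:
    """Per-lineage (expression rate, elongation rate) series for one movie.

    Expression rates are differentiated from the movie smoothed with the
    mother/daughter-padded filter; elongation rates from raw lengths via
    stitching (shared segments remain identical across lineages).  The window
    defaults to one-third of the colony's mean completed cycle time.
    """
    from .traces import smooth_movie

    if window_h is None:
        window_h = mean_cycle_time(table) / 3.0
    sm = smoothed_table if smoothed_table is not None else smooth_movie(table, "yfp")
    expr = [expression_rate(tr) for tr in extract_lineages(sm, "yfp")]
    elong = [
        elongation_rate(tr, window_h=window_h)
        for tr in extract_lineages(table, "length")
    ]
    return expr, elong


def movie_rate_table(table: MovieTable, window_h: float | None = None) -> pd.DataFrame:
    """Tidy per-cell, per-frame rate table (each cell counted once).

    Every cell's frames are taken from the first depth-first lineage that
    contains the cell, so shared ancestral prefixes are not duplicated.
    Columns: time_h, cell_id, elong_rate_per_h, expr_rate_au_per_h.
    """
    expr, elong = movie_rate_traces(table, window_h=window_h)
    rows = {}
    for ex, el in zip(expr, elong):
        for i, cid in enumerate(el.segment_ids):
            k = (int(cid), float(el.times[i]))
            if k not in rows:
                rows[k] = (el.rate[i], ex.rate[i])
    data = [
        {"time_h": tk, "cell_id": ck, "elong_rate_per_h": er, "expr_rate_au_per_h": xr}
        for (ck, tk), (er, xr) in sorted(rows.items())
    ]
    return pd.DataFrame(data)


def colony_mean_rates(rate_table: pd.DataFrame) -> pd.DataFrame:
    """Frame-wise mean over cells alive at each frame."""
    return (
        rate_table.groupby("time_h", as_index=False)[
            ["elong_rate_per_h", "expr_rate_au_per_h"]
        ]
        .mean()
        .sort_values("time_h", ignore_index=True)
    )
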