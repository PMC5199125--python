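"""High-level per-movie analysis: generation -> traces -> peaks -> rates ->
correlations, as composable functions returning in-memory results.

These are the steps the command-line interface and the reproduction script
chain together; each wraps the corresponding lower-level module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import movie_rate_traces
from .lineages import MovieTable
from .peaks import CircadianWindow, PeakPair, amplitude_stats, analyze_lineage_windows, peak_to_peak
from .traces import CosinorFit, Trace, cosinor_fit_many, detrend, extract_lineages, smooth_movie
from .treecorr import CorrelationResult, average_movies, tree_xcorr

__all__ = [
    "MoviePeakAnalysis",
    "analyze_movie_peaks",
    "pair_distances",
    "distance_mode",
    "rate_matrices",
    "rate_correlation",
]


@dataclass
class MoviePeakAnalysis:
    """Everything the peak pipeline produces for one movie."""

    traces: list[Trace]
    fits: list[CosinorFit]
    windows: list[list[CircadianWindow]]
    pairs: list[PeakPair]

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lineage_id": [p.lineage_id for p in self.pairs],
                "t1_h": [p.first.time_h for p in self.pairs],
                "t2_h": [p.second.time_h for p in self.pairs],
                "distance_h": [p.distance_h for p in self.pairs],
                "same_window": [p.same_window for p in self.pairs],
            }
        )

    def fits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lineage_id": [t.lineage_id for t in self.traces],
                "alpha": [f.alpha for f in self.fits],
                "beta": [f.beta for f in self.fits],
                "phi_h": [f.phi for f in self.fits],
                "tau_h": [f.tau for f in self.fits],
                "sse": [f.sse for f in self.fits],
            }
        )

    def peaks_frame(self) -> pd.DataFrame:
        rows = []
        for wins in self.windows:
            for j, w in enumerate(wins):
                for p in w.peaks or []:
                    rows.append(
                        {
                            "lineage_id": w.lineage_id,
                            "window_index": j,
                            "time_h": p.time_h,
                            "height": p.height,
                            "prominence": p.prominence,
                            "width_h": p.width_h,
                        }
                    )
        return pd.DataFrame(rows)

    def amplitude_summary(self) -> dict:
        return amplitude_stats(self.windows)


def analyze_movie_peaks(table: MovieTable, combine: str = "or") -> MoviePeakAnalysis:
    """Run smoothing, detrending, cosinor windowing, peak detection/filtering
    and unique peak-to-peak measurement for one movie."""
    sm = smooth_movie(table, "yfp")
    traces = extract_lineages(sm, "yfp")
    grid = traces[0].times
    if all(len(t) == len(grid) for t in traces):
        det = np.vstack([detrend(t.times, t.values) for t in traces])
        fits = cosinor_fit_many(grid, det)
    else:  # uneven lineages: fit one by one
        fits = [
            cosinor_fit_many(t.times, detrend(t.times, t.values)[None, :])[0]
            for t in traces
        ]
    windows = [analyze_lineage_windows(t, f, combine=combine) for t, f in zip(traces, fits)]
    pairs = peak_to_peak(windows, sample_interval_h=table.config.sample_interval_h)
    return MoviePeakAnalysis(traces=traces, fits=fits, windows=windows, pairs=pairs)


def pair_distances(
    analyses: list[MoviePeakAnalysis], same_window: bool | None = None
) -> np.ndarray:
    """Pool unique peak-to-peak distances over movies, optionally keeping
    only within-window (True) or cross-window (False) pairs."""
    out = []
    for a in analyses:
        for p in a.pairs:
            if same_window is None or p.same_window == same_window:
                out.append(p.distance_h)
    return np.array(out)


def distance_mode(distances: np.ndarray, bin_h: float = 0.75) -> float:
    """Mode of a distance distribution on the sampling grid."""
    if distances.size == 0:
        raise ValueError("no distances to take a mode over")
    bins = np.round(distances / bin_h).astype(int)
    vals, counts = np.unique(bins, return_counts=True)
    return float(vals[np.argmax(counts)] * bin_h)


def rate_matrices(table: MovieTable) -> tuple[np.ndarray, np.ndarray]:
    """(expression-rate, elongation-rate) lineage matrices for one movie."""
    expr, elong = movie_rate_traces(table)
    X = np.vstack([r.rate for r in expr])
    Y = np.vstack([r.rate for r in elong])
    return X, Y

def rate_correlation(
    tables: list[MovieTable],
    x: str = "expr_rate",
    y: str = "elong_rate",
    lag_max_h: float = 48.0,
    centring: str = "lineage",
) -> CorrelationResult:
    """Averaged tree-corrected correlation of rate signals across movies.

    ``x``/``y`` each name a signal: "expr_rate" or "elong_rate"; use the same
    name twice for an auto-correlation.
    """
    results = []
    for table in tables:
        X_expr, Y_elong = rate_matrices(table)
        pick = {"expr_rate": X_expr, "elong_rate": Y_elong}
        try:
            X, Y = pick[x], pick[y]
        except KeyError as e:
            raise ValueError(f"unknown signal {e.args[0]!r}") from None
        dt = table.config.sample_interval_h
        results.append(tree_xcorr(X, Y, dt=dt, lag_max_h=lag_max_h, centring=centring))
    return average_movies(results)
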