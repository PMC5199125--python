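"""Circadian-window peak analysis.

Each lineage's cosinor fit defines *circadian windows*: the intervals
between consecutive troughs of the fitted sinusoid.  Within each window,
candidate expression peaks are detected, then filtered by the study's rules:

* peaks at least 3 h apart (the lower of any closer pair is dropped,
  keeping the highest first);
* full width at half maximum (measured above the window minimum) >= 2 h;
* once a major peak exists, peaks with height < 25% of the major's or
  prominence < 10% of the major's prominence are discarded (OR is the
  default, the stricter reading; AND is available);
* a retained peak whose FWHM differs from the major's by more than 5 h is
  discarded (the major peak is always kept).

Peak-to-peak distances are measured between consecutive peaks within a
window, or from a lone peak to the first peak of the next window; distances
above 36 h are dropped, and pairs duplicated across lineages through shared
ancestral segments are de-duplicated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .traces import CosinorFit, Trace

__all__ = [
    "Peak",
    "CircadianWindow",
    "PeakPair",
    "circadian_windows",
    "detect_peaks",
    "filter_peaks",
    "peak_to_peak",
    "amplitude_stats",
    "analyze_lineage_windows",
]


@dataclass(frozen=True)
class Peak:
    time_h: float
    height: float
    prominence: float
    width_h: float  # FWHM above the window minimum
    cell_id: int = -1


@dataclass
class CircadianWindow:
    """One trough-to-trough interval of a lineage with its retained peaks."""

    lineage_id: str
    start_h: float
    end_h: float
    times: np.ndarray
    values: np.ndarray
    segment_ids: np.ndarray
    peaks: list[Peak] | None = None


@dataclass(frozen=True)
class PeakPair:
    first: Peak
    second: Peak
    distance_h: float
    same_window: bool
    lineage_id: str


def circadian_windows(fit: CosinorFit, t_range: tuple[float, float]) -> list[tuple[float, float]]:
    """Trough-to-trough intervals of the fitted sinusoid inside ``t_range``.

    Troughs sit where the cosine term equals -1, i.e. at
    t = tau/2 - phi + k*tau, spaced exactly tau apart; only windows fully
    inside the range are returned.
    """
    t0, t1 = t_range
    if t1 - t0 < fit.tau:
        return []
    first = fit.tau / 2.0 - fit.phi
    k0 = math.ceil((t0 - first) / fit.tau - 1e-9)
    troughs = []
    k = k0
    while first + k * fit.tau <= t1 + 1e-9:
        troughs.append(first + k * fit.tau)
        k += 1
    return [(troughs[i], troughs[i + 1]) for i in range(len(troughs) - 1)]


def _fwhm(times: np.ndarray, values: np.ndarray, idx: int) -> float:
    """Full width at half maximum, half-height relative to the window minimum.

    Crossing times are linearly interpolated.  Walking outwards from the
    peak, entering terrain taller than the peak itself (an overlapping
    higher peak) truncates the width at the intervening valley, so a
    secondary peak's width does not swallow its larger neighbour; where the
    signal never drops below half height the width extends to the window
    edge.
    """
    base = float(values.min())
    half = base + 0.5 * (values[idx] - base)
    peak_h = values[idx]

    def walk(step: int) -> float:
        edge = times[0] if step < 0 else times[-1]
        valley_j = idx
        j = idx
        while 0 < j if step < 0 else j < len(values) - 1:
            nxt = j + step
            if values[nxt] < half <= values[j]:
                frac = (values[j] - half) / (values[j] - values[nxt])
                return float(times[j] + frac * (times[nxt] - times[j]))
            if values[nxt] > peak_h:  # taller neighbour: clip at the valley
                return float(times[valley_j])
            if values[nxt] < values[valley_j]:
                valley_j = nxt
            j = nxt
        return float(edge)

    return walk(+1) - walk(-1)


def detect_peaks(
    times: np.ndarray,
    values: np.ndarray,
    segment_ids: np.ndarray | None = None,
    min_separation_h: float = 3.0,
    min_fwhm_h: float = 2.0,
) -> list[Peak]:
    """Candidate peaks of one window: local maxima with separation and width rules.

    Strict local maxima (plateaus yield their centre sample); any two
    candidates closer than ``min_separation_h`` lose the lower one (highest
    kept first); candidates with FWHM below ``min_fwhm_h`` are dropped.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        return []
    idx, props = find_peaks(v, plateau_size=(1, None))
    # centre sample of flat-topped runs
    idx = ((props["left_edges"] + props["right_edges"]) // 2).astype(int)
    if len(idx) == 0:
        return []
    prom = peak_prominences(v, idx)[0]
    # enforce minimum separation, keeping higher peaks first
    order = sorted(range(len(idx)), key=lambda k: (-v[idx[k]], idx[k]))
    kept: list[int] = []
    for k in order:
        if all(abs(t[idx[k]] - t[idx[j]]) >= min_separation_h for j in kept):
            kept.append(k)
    peaks = []
    for k in sorted(kept, key=lambda k: idx[k]):
        width = _fwhm(t, v, int(idx[k]))
        if width < min_fwhm_h:
            continue
        cid = int(segment_ids[idx[k]]) if segment_ids is not None else -1
        peaks.append(
            Peak(
                time_h=float(t[idx[k]]),
                height=float(v[idx[k]]),
                prominence=float(prom[k]),
                width_h=width,
                cell_id=cid,
            )
        )
    return peaks


def filter_peaks(
    candidates: list[Peak],
    height_frac: float = 0.25,
    prominence_frac: float = 0.10,
    max_width_diff_h: float = 5.0,
    combine: str = "or",
) -> list[Peak]:
    """Apply the relative height/prominence and width-difference rules.

    The major peak is the highest candidate and is always retained.  With
    ``combine='or'`` (default, the stricter reading) a minor peak is dropped
    when its height falls below ``height_frac`` of the major's OR its
    prominence below ``prominence_frac`` of the major's; with ``'and'`` both
    must fail.  A surviving peak whose FWHM differs from the major's by more
    than ``max_width_diff_h`` is then dropped.
    """
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")
    if not candidates:
        return []
    major = max(candidates, key=lambda p: (p.height, -p.time_h))
    out = []
    for p in candidates:
        if p is major:
            out.append(p)
            continue
        low_h = p.height < height_frac * major.height
        low_p = p.prominence < prominence_frac * major.prominence
        drop = (low_h or low_p) if combine == "or" else (low_h and low_p)
        if drop:
            continue
        if abs(p.width_h - major.width_h) > max_width_diff_h:
            continue
        out.append(p)
    return sorted(out, key=lambda p: p.time_h)


def analyze_lineage_windows(
    trace: Trace,
    fit: CosinorFit,
    detrended: np.ndarray | None = None,
    combine: str = "or",
) -> list[CircadianWindow]:
    """Slice a lineage into circadian windows and attach retained peaks.

    Windows come from the cosinor fit (of the detrended trace); peaks are
    detected on the trace values themselves.
    """
    windows = []
    for (w0, w1) in circadian_windows(fit, (trace.times[0], trace.times[-1])):
        m = (trace.times >= w0 - 1e-9) & (trace.times <= w1 + 1e-9)
        if m.sum() < 5:
            continue
        win = CircadianWindow(
            lineage_id=trace.lineage_id,
            start_h=w0,
            end_h=w1,
            times=trace.times[m],
            values=trace.values[m],
            segment_ids=trace.segment_ids[m],
        )
        cand = detect_peaks(win.times, win.values, win.segment_ids)
        win.peaks = filter_peaks(cand, combine=combine)
        windows.append(win)
    return windows


def peak_to_peak(
    lineage_windows: list[list[CircadianWindow]],
    sample_interval_h: float = 0.75,
    max_distance_h: float = 36.0,
) -> list[PeakPair]:
    """Unique consecutive-peak distances across all lineages of one movie.

    Within multi-peak windows, consecutive in-window distances are taken;
    a lone peak is paired with the first peak of the next window.  Distances
    above ``max_distance_h`` are dropped.  Because sibling lineages duplicate
    their shared ancestral windows, pairs are de-duplicated on (first time,
    second time, first cell, second cell) with times rounded to the sampling
    grid.
    """
    pairs: list[PeakPair] = []
    seen: set[tuple] = set()

    def key(p: Peak, q: Peak) -> tuple:
        r = sample_interval_h
        return (round(p.time_h / r), round(q.time_h / r), p.cell_id, q.cell_id)

    for windows in lineage_windows:
        for j, win in enumerate(windows):
            ps = win.peaks or []
            if len(ps) >= 2:
                for a, b in zip(ps[:-1], ps[1:]):
                    d = b.time_h - a.time_h
                    if 0.0 < d <= max_distance_h and key(a, b) not in seen:
                        seen.add(key(a, b))
                        pairs.append(PeakPair(a, b, d, True, win.lineage_id))
            elif len(ps) == 1 and j + 1 < len(windows):
                nxt = windows[j + 1].peaks or []
                if nxt:
                    a, b = ps[0], nxt[0]
                    d = b.time_h - a.time_h
                    if 0.0 < d <= max_distance_h and key(a, b) not in seen:
                        seen.add(key(a, b))
                        pairs.append(PeakPair(a, b, d, False, win.lineage_id))
    return pairs


def amplitude_stats(lineage_windows: list[list[CircadianWindow]]) -> dict:
    """Peak-height summaries: all heights, and first-minus-second height
    differences over double-peak windows (time-ordered)."""
    heights = []
    diffs = []
    for windows in lineage_windows:
        for win in windows:
            ps = win.peaks or []
            heights.extend(p.height for p in ps)
            if len(ps) >= 2:
                diffs.append(ps[0].height - ps[1].height)
    heights = np.array(heights)
    diffs = np.array(diffs)
    return {
        "heights": heights,
        "height_mean": float(heights.mean()) if heights.size else math.nan,
        "height_sd": float(heights.std(ddof=1)) if heights.size > 1 else math.nan,
        "diffs": diffs,
        "diff_mean": float(diffs.mean()) if diffs.size else math.nan,
        "diff_sd": float(diffs.std(ddof=1)) if diffs.size > 1 else math.nan,
    }
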