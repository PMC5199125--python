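"""Movie tables -> analysis-ready single-cell lineage traces.

A *lineage* is one root-to-leaf path through the division tree with each
cell's frames concatenated in time; sibling lineages share their ancestral
prefix (the tree-correlation estimator corrects for that duplication).

Signal conditioning follows the study's microscopy pipeline: per-cell
5-point (3 h) moving-average smoothing, with windows that straddle a cell's
first/last two frames completed using the mother's trailing frames on the
left and the two daughters' average on the right (shrinking symmetrically
where those cells were not captured); quadratic detrending; and a cosinor
fit -- the best single-period sinusoid

    F(t) = alpha + beta * cos(2*pi*(t + phi)/tau),   tau in [21, 27] h,

found by closed-form least squares on a cos/sin basis at each candidate
period on a 0.01-h grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lineages import MovieTable

__all__ = [
    "Trace",
    "CosinorFit",
    "extract_lineages",
    "smooth_segment",
    "smooth_movie",
    "detrend",
    "cosinor_fit",
    "cosinor_fit_many",
]

TAU_GRID = np.round(np.arange(21.0, 27.0 + 1e-9, 0.01), 2)


class TraceError(ValueError):
    pass


@dataclass
class Trace:
    """One root-to-leaf lineage series on the movie's uniform frame grid."""

    lineage_id: str
    times: np.ndarray
    values: np.ndarray
    segment_ids: np.ndarray  # owning cell id per frame
    branch_times: np.ndarray  # division times along the path (h)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class CosinorFit:
    """Constrained single-period sinusoid fit (mesor alpha, amplitude
    beta >= 0, acrophase phi in [0, tau), period tau in [21, 27] h)."""

    alpha: float
    beta: float
    phi: float
    tau: float
    sse: float

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.alpha + self.beta * np.cos(2.0 * np.pi * (t + self.phi) / self.tau)


def _leaf_paths(table: MovieTable) -> list[list[int]]:
    children = table.children_map()
    paths: list[list[int]] = []
    for root in table.roots():
        stack: list[list[int]] = [[root.cell_id]]
        while stack:
            path = stack.pop()
            kids = children.get(path[-1], [])
            if not kids:
                paths.append(path)
            else:
                # push in reverse so lower cell ids are visited first (DFS)
                for kid in reversed(kids):
                    stack.append(path + [kid])
    return paths


def extract_lineages(table: MovieTable, signal: str = "yfp") -> list[Trace]:
    """One trace per root-to-leaf path, depth-first order.

    ``signal`` selects the per-frame quantity: "yfp" or "length".
    """
    if signal not in ("yfp", "length"):
        raise ValueError("signal must be 'yfp' or 'length'")
    traces = []
    for path in _leaf_paths(table):
        times, values, seg = [], [], []
        branch = []
        for cid in path:
            cell = table.cell(cid)
            if cell.parent_id is not None and cell.parent_id not in {c.cell_id for c in table.cells}:
                raise TraceError(f"cell {cid} has a broken parent link")
            v = cell.yfp if signal == "yfp" else cell.lengths
            if v is None:
                raise TraceError(f"cell {cid} has no {signal} data")
            times.append(cell.times)
            values.append(np.asarray(v, dtype=float))
            seg.append(np.full(len(cell.times), cid))
            if cell.division_time_h is not None and cid != path[-1]:
                branch.append(cell.division_time_h)
        traces.append(
            Trace(
                lineage_id=f"c{table.colony_id}-l{path[-1]}",
                times=np.concatenate(times),
                values=np.concatenate(values),
                segment_ids=np.concatenate(seg),
                branch_times=np.array(branch),
            )
        )
    return traces


def smooth_segment(
    values: np.ndarray,
    left: np.ndarray | None = None,
    right: np.ndarray | None = None,
    window: int = 5,
) -> np.ndarray:
    """Centered moving average of one cell-cycle segment.

    ``left``/``right`` carry up to ``window//2`` padding samples from the
    mother (its last frames) and the averaged daughters (their first frames).
    Where padding is unavailable the window shrinks symmetrically so that the
    filter stays centered and unbiased for linear trends.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v.copy()
    half = window // 2
    lpad = np.asarray(left, dtype=float)[-half:] if left is not None and len(left) else np.empty(0)
    rpad = np.asarray(right, dtype=float)[:half] if right is not None and len(right) else np.empty(0)
    ext = np.concatenate([lpad, v, rpad])
    off = len(lpad)
    out = np.empty_like(v)
    for i in range(len(v)):
        j = off + i
        h = min(half, j, len(ext) - 1 - j)
        out[i] = ext[j - h : j + h + 1].mean()
    return out


def smooth_movie(table: MovieTable, signal: str = "yfp", window: int = 5) -> MovieTable:
    """Smooth every cell's trace in place-free fashion (returns a new table).

    Padding uses the mother's trailing frames on the left and the elementwise
    average of the two daughters' leading frames on the right, when acquired.
    Smoothing per cell (rather than per lineage) makes shared ancestral
    segments identical across lineages, which downstream de-duplication and
    the tree-corrected correlation rely on.
    """
    import copy

    if signal not in ("yfp", "length"):
        raise ValueError("signal must be 'yfp' or 'length'")
    new = copy.deepcopy(table)
    children = new.children_map()
    half = window // 2

    def data(cell):
        return cell.yfp if signal == "yfp" else cell.lengths

    for cell in new.cells:
        v = data(cell)
        if v is None:
            raise TraceError(f"cell {cell.cell_id} has no {signal} data")
        left = None
        if cell.parent_id is not None:
            left = data(new.cell(cell.parent_id))
        kids = children.get(cell.cell_id, [])
        right = None
        if kids:
            kid_data = [np.asarray(data(new.cell(k)), dtype=float)[:half] for k in kids]
            n = min((len(k) for k in kid_data), default=0)
            if n > 0:
                right = np.mean([k[:n] for k in kid_data], axis=0)
        sm = smooth_segment(np.asarray(v, dtype=float), left, right, window)
        if signal == "yfp":
            cell.yfp = sm
        else:
            cell.lengths = sm
    return new


def detrend(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Residuals of the least-squares quadratic in time.

    The output has zero mean and is orthogonal to {1, t, t^2}.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 3:
        raise TraceError("detrending needs at least 3 points")
    # centre time for conditioning
    tc = t - t.mean()
    coeffs = np.polynomial.polynomial.polyfit(tc, v, 2)
    return v - np.polynomial.polynomial.polyval(tc, coeffs)


def _design(times: np.ndarray, tau: float) -> np.ndarray:
    ang = 2.0 * np.pi * times / tau
    return np.column_stack([np.ones_like(times), np.cos(ang), np.sin(ang)])


def cosinor_fit_many(
    times: np.ndarray, values: np.ndarray, tau_grid: np.ndarray = TAU_GRID
) -> list[CosinorFit]:
    """Cosinor-fit many series sharing one time grid (rows of ``values``).

    For each candidate period the mesor/amplitude/phase minimising squared
    error have a closed form (linear regression on a cos/sin basis); the grid
    search over tau makes the period estimate deterministic and free of local
    minima.  Series must span at least 36 h.
    """
    t = np.asarray(times, dtype=float)
    V = np.atleast_2d(np.asarray(values, dtype=float))
    if t[-1] - t[0] < 36.0:
        raise TraceError("cosinor fit needs a trace spanning at least 36 h")
    best_sse = np.full(V.shape[0], np.inf)
    best = np.zeros((V.shape[0], 3))
    best_tau = np.full(V.shape[0], tau_grid[0])
    for tau in tau_grid:
        X = _design(t, tau)
        coef, *_ = np.linalg.lstsq(X, V.T, rcond=None)
        resid = V.T - X @ coef
        sse = np.sum(resid * resid, axis=0)
        better = sse < best_sse - 1e-12
        best_sse = np.where(better, sse, best_sse)
        best_tau = np.where(better, tau, best_tau)
        best[better] = coef.T[better]
    fits = []
    for k in range(V.shape[0]):
        a, bc, bs = best[k]
        tau = float(best_tau[k])
        beta = math.hypot(bc, bs)
        psi = math.atan2(-bs, bc)  # F = a + beta*cos(2*pi*t/tau + psi)
        phi = (psi * tau / (2.0 * math.pi)) % tau
        fits.append(CosinorFit(float(a), beta, phi, tau, float(best_sse[k])))
    return fits


def cosinor_fit(trace_or_times, values=None, tau_grid: np.ndarray = TAU_GRID) -> CosinorFit:
    """Cosinor-fit one series; accepts a Trace or (times, values)."""
    if values is None:
        t, v = trace_or_times.times, trace_or_times.values
    else:
        t, v = trace_or_times, values
    return cosinor_fit_many(t, v, tau_grid)[0]
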