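"""Synthetic lineage-movie generator.

Emulates time-lapse microscopy of rod-shaped cyanobacteria growing as a
micro-colony: exponentially elongating cells that divide roughly in half,
carry a fluorescent reporter with a circadian (24-h) waveform -- optionally
frequency-doubled with a second, smaller peak ~9 h after the first -- and
whose instantaneous elongation rate is modulated by the same circadian
programme with a configurable delay relative to the expression rate.

The generator is timer-based (each cell draws its cycle time at birth from a
truncated normal), cells inherit their mother's circadian phase plus a small
per-cycle diffusion term (which desynchronises the colony and hides the
second peak in population averages), fluorescence carries multiplicative
measurement noise, and lengths are noise-free (segmentation noise is not
emulated).  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "CellRecord",
    "MovieTable",
    "PRESETS",
    "grow_tree",
    "expression_waveform",
    "expression_waveform_deriv",
    "growth_modulation_waveform",
    "attach_fluorescence",
    "attach_growth",
    "generate_movie",
    "generate_movies",
]

# Preset growth statistics are the study's measured values at each light level
# (cycle time mean/sd in h, elongation rate mean/sd in 1/h); reporter presets
# encode the qualitative waveform of each strain: the sigC knock-outs lose the
# second psbAI peak and gain amplitude, the sigC reporter itself is
# single-peaked with a 3.5-fold amplitude gain in the knock-out, and rpoD6
# carries a weaker secondary bump.
PRESETS: dict[str, dict] = {
    "WT_LOW": dict(mean_cycle_h=19.5, sd_cycle_h=4.6,
                   mean_elong_rate_per_h=0.031, sd_elong_rate_per_h=0.004,
                   second_peak_rel_amp=0.6, amplitude_factor=1.0),
    "SIGC_KO_LOW": dict(mean_cycle_h=19.5, sd_cycle_h=4.6,
                        mean_elong_rate_per_h=0.031, sd_elong_rate_per_h=0.004,
                        second_peak_rel_amp=0.0, amplitude_factor=1.4),
    "WT_HIGH": dict(mean_cycle_h=9.3, sd_cycle_h=2.7,
                    mean_elong_rate_per_h=0.07, sd_elong_rate_per_h=0.01,
                    second_peak_rel_amp=0.15, amplitude_factor=1.0),
    "SIGC_KO_HIGH": dict(mean_cycle_h=9.3, sd_cycle_h=2.7,
                         mean_elong_rate_per_h=0.07, sd_elong_rate_per_h=0.01,
                         second_peak_rel_amp=0.0, amplitude_factor=1.0),
    "WT_VERYLOW": dict(mean_cycle_h=25.2, sd_cycle_h=5.8,
                       mean_elong_rate_per_h=0.025, sd_elong_rate_per_h=0.004,
                       second_peak_rel_amp=0.6, amplitude_factor=1.0),
    "RPOD6_WT": dict(mean_cycle_h=19.5, sd_cycle_h=4.6,
                     mean_elong_rate_per_h=0.031, sd_elong_rate_per_h=0.004,
                     second_peak_rel_amp=0.3, amplitude_factor=1.0),
    "RPOD6_KO": dict(mean_cycle_h=19.5, sd_cycle_h=4.6,
                     mean_elong_rate_per_h=0.031, sd_elong_rate_per_h=0.004,
                     second_peak_rel_amp=0.0, amplitude_factor=1.0),
    "SIGC_REPORTER_WT": dict(mean_cycle_h=19.5, sd_cycle_h=4.6,
                             mean_elong_rate_per_h=0.031, sd_elong_rate_per_h=0.004,
                             second_peak_rel_amp=0.0, amplitude_factor=1.0),
    "SIGC_REPORTER_KO": dict(mean_cycle_h=19.5, sd_cycle_h=4.6,
                             mean_elong_rate_per_h=0.031, sd_elong_rate_per_h=0.004,
                             second_peak_rel_amp=0.0, amplitude_factor=3.5),
}


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the movie generator; time in hours, lengths in microns."""

    preset: str = "WT_LOW"
    mean_cycle_h: float = 19.5
    sd_cycle_h: float = 4.6
    mean_elong_rate_per_h: float = 0.031
    sd_elong_rate_per_h: float = 0.004
    sample_interval_h: float = 0.75   # 45-min imaging cadence
    duration_h: float = 120.0
    n_colonies: int = 1
    clock_period_h: float = 24.0
    second_peak_delay_h: float = 9.0
    second_peak_rel_amp: float = 0.6
    amplitude_factor: float = 1.0
    peak_fwhm_h: float = 6.0
    baseline_au: float = 0.2
    phase_diffusion_sd_h_per_cycle: float = 1.0
    meas_noise_cv: float = 0.05
    growth_mod_depth: float = 0.3
    growth_lag_h: float = 1.0
    partition_sd: float = 0.02
    initial_length_um: float = 2.0
    min_cycle_h: float = 2.0
    max_cells: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h < self.sample_interval_h:
            raise GeneratorConfigError("duration shorter than one sampling interval")
        if not (0.0 <= self.second_peak_rel_amp <= 1.0):
            raise GeneratorConfigError("second_peak_rel_amp must be in [0, 1]")
        if not (0.0 <= self.growth_mod_depth <= 1.0):
            raise GeneratorConfigError("growth_mod_depth must be in [0, 1]")
        if self.sample_interval_h <= 0 or self.mean_cycle_h <= 0:
            raise GeneratorConfigError("intervals and cycle times must be positive")

    @staticmethod
    def from_preset(name: str, **overrides) -> "GeneratorConfig":
        if name not in PRESETS:
            raise GeneratorConfigError(
                f"unknown preset {name!r}; expected one of {sorted(PRESETS)}"
            )
        kwargs = dict(PRESETS[name])
        kwargs.update(overrides)
        return GeneratorConfig(preset=name, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellRecord:
    """One segmented-and-tracked cell: identity, tree links and per-frame data."""

    cell_id: int
    parent_id: Optional[int]
    birth_time_h: float
    division_time_h: Optional[float]  # None if censored at movie end
    birth_length_um: float
    phase_h: float
    base_rate_per_h: float
    birth_fraction: float  # fraction of the mother's division length received
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    yfp: Optional[np.ndarray] = None

    @property
    def completed(self) -> bool:
        return self.division_time_h is not None

    @property
    def cycle_time_h(self) -> Optional[float]:
        if self.division_time_h is None:
            return None
        return self.division_time_h - self.birth_time_h


@dataclass
class MovieTable:
    """One micro-colony movie: a binary forest of cell records plus metadata."""

    colony_id: int
    cells: list[CellRecord]
    config: GeneratorConfig
    seed: int

    def __post_init__(self) -> None:
        self._by_id = {c.cell_id: c for c in self.cells}

    def cell(self, cell_id: int) -> CellRecord:
        return self._by_id[cell_id]

    def children(self, cell_id: int) -> list[CellRecord]:
        return [c for c in self.cells if c.parent_id == cell_id]

    def roots(self) -> list[CellRecord]:
        return [c for c in self.cells if c.parent_id is None]

    def children_map(self) -> dict[Optional[int], list[int]]:
        out: dict[Optional[int], list[int]] = {}
        for c in self.cells:
            out.setdefault(c.parent_id, []).append(c.cell_id)
        return out

    def completed_cycle_times(self) -> np.ndarray:
        return np.array([c.cycle_time_h for c in self.cells if c.completed])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-frame table (colony_id, cell_id, parent_id, time_h,
        length_um, yfp_au)."""
        rows = []
        for c in self.cells:
            yfp = c.yfp if c.yfp is not None else np.full_like(c.times, np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "colony_id": self.colony_id,
                        "cell_id": c.cell_id,
                        "parent_id": -1 if c.parent_id is None else c.parent_id,
                        "time_h": c.times,
                        "length_um": c.lengths,
                        "yfp_au": yfp,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _draw_cycle_time(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    """Truncated normal cycle time (> min_cycle_h) by rejection.

    In an exponentially growing colony, completed cycles observed in the tree
    over-represent fast-cycling lineages (each short cycle spawns more
    descendants), biasing the realised mean below the timer's mean by about
    ln(2) * sd^2 / mean.  The draw compensates to first order so the
    *measured* completed-cycle statistics match the configured values.
    """
    mu = cfg.mean_cycle_h + math.log(2.0) * cfg.sd_cycle_h**2 / cfg.mean_cycle_h
    while True:
        t = rng.normal(mu, cfg.sd_cycle_h)
        if t > cfg.min_cycle_h:
            return float(t)


def _beta_ab(sd: float) -> float:
    # symmetric Beta(a, a) with the requested sd around 0.5
    return (1.0 / (4.0 * sd * sd) - 1.0) / 2.0


def grow_tree(
    config: GeneratorConfig,
    colony_id: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> MovieTable:
    """Grow one colony's division tree with pure exponential elongation.

    Frames lie on the global grid k*sample_interval_h; a cell owns the grid
    points in [birth, division).  Circadian phases are assigned here (founder
    uniform over the clock period, daughters inherit the mother's phase plus
    a normal per-cycle diffusion step) so that fluorescence and growth
    modulation later agree cell by cell.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, colony_id])
    dt = cfg.sample_interval_h
    n_frames = int(math.floor(cfg.duration_h / dt + 1e-9))
    t_grid = dt * np.arange(n_frames + 1)
    movie_end = float(t_grid[-1])
    beta_a = _beta_ab(cfg.partition_sd)

    cells: list[CellRecord] = []
    next_id = 0
    founder_phase = float(rng.uniform(0.0, cfg.clock_period_h))
    # FIFO queue keeps creation order deterministic
    queue: list[tuple[float, float, Optional[int], float, float]] = [
        (0.0, cfg.initial_length_um, None, founder_phase, 1.0)
    ]
    while queue:
        birth, birth_len, parent, phase, fraction = queue.pop(0)
        if birth >= movie_end:
            continue
        if len(cells) >= cfg.max_cells:
            raise GeneratorConfigError(
                f"colony exceeded max_cells={cfg.max_cells}; shorten duration_h"
            )
        base_rate = float(rng.normal(cfg.mean_elong_rate_per_h, cfg.sd_elong_rate_per_h))
        base_rate = max(base_rate, 1e-4)
        cycle = _draw_cycle_time(rng, cfg)
        division: Optional[float] = birth + cycle
        if division >= movie_end:
            division = None
        lo = t_grid >= birth - 1e-9
        hi = t_grid < (division if division is not None else np.inf) - 1e-9
        times = t_grid[lo & hi]
        cell = CellRecord(
            cell_id=next_id,
            parent_id=parent,
            birth_time_h=birth,
            division_time_h=division,
            birth_length_um=birth_len,
            phase_h=phase,
            base_rate_per_h=base_rate,
            birth_fraction=fraction,
            times=times,
            lengths=birth_len * np.exp(base_rate * (times - birth)),
        )
        cells.append(cell)
        next_id += 1
        if division is not None:
            div_len = birth_len * math.exp(base_rate * cycle)
            f = float(rng.beta(beta_a, beta_a))
            for frac in (f, 1.0 - f):
                child_phase = phase + float(
                    rng.normal(0.0, cfg.phase_diffusion_sd_h_per_cycle)
                )
                queue.append((division, frac * div_len, cell.cell_id, child_phase, frac))
    return MovieTable(colony_id=colony_id, cells=cells, config=cfg, seed=cfg.seed)


def _bump_sum(x: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Periodicised pair of Gaussian bumps evaluated at circadian coordinate x."""
    period = cfg.clock_period_h
    sigma = cfg.peak_fwhm_h / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    x = np.mod(x, period)
    out = np.zeros_like(x)
    for k in (-1.0, 0.0, 1.0):
        out += np.exp(-((x - k * period) ** 2) / (2.0 * sigma**2))
        if cfg.second_peak_rel_amp > 0:
            out += cfg.second_peak_rel_amp * np.exp(
                -((x - cfg.second_peak_delay_h - k * period) ** 2) / (2.0 * sigma**2)
            )
    return cfg.amplitude_factor * out


def _bump_sum_deriv(x: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    period = cfg.clock_period_h
    sigma = cfg.peak_fwhm_h / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    x = np.mod(x, period)
    out = np.zeros_like(x)
    for k in (-1.0, 0.0, 1.0):
        d = x - k * period
        out += -d / sigma**2 * np.exp(-(d**2) / (2.0 * sigma**2))
        if cfg.second_peak_rel_amp > 0:
            d2 = x - cfg.second_peak_delay_h - k * period
            out += (
                cfg.second_peak_rel_amp
                * (-d2 / sigma**2)
                * np.exp(-(d2**2) / (2.0 * sigma**2))
            )
    return cfg.amplitude_factor * out


def expression_waveform(t, phase_h: float, config: GeneratorConfig) -> np.ndarray:
    """Relative promoter activity at time t for a cell with the given phase.

    Clock-period-periodic and non-negative: a primary unit-height Gaussian
    bump (FWHM ``peak_fwhm_h``) peaking at t = phase (mod period), plus, for
    double-peak presets, a secondary bump of relative height
    ``second_peak_rel_amp`` centred ``second_peak_delay_h`` later.  The whole
    waveform is scaled by the preset's ``amplitude_factor``.
    """
    t = np.asarray(t, dtype=float)
    return _bump_sum(t - phase_h, config)


def expression_waveform_deriv(t, phase_h: float, config: GeneratorConfig) -> np.ndarray:
    """Time derivative of :func:`expression_waveform` (a.u./h)."""
    t = np.asarray(t, dtype=float)
    return _bump_sum_deriv(t - phase_h, config)


def _deriv_max_abs(cfg: GeneratorConfig) -> float:
    grid = np.arange(0.0, cfg.clock_period_h, 0.01)
    m = float(np.max(np.abs(_bump_sum_deriv(grid, cfg))))
    return m if m > 0 else 1.0


def growth_modulation_waveform(t, phase_h: float, config: GeneratorConfig) -> np.ndarray:
    """Zero-mean, unit-max-abs expression-rate waveform driving growth.

    This is the normalised time derivative of the expression waveform: the
    elongation rate is modulated by the *rate* of expression, delayed by
    ``growth_lag_h`` (applied by the caller), so growth peaks trail expression
    peaks as observed in the cross-correlation analysis.
    """
    t = np.asarray(t, dtype=float)
    return _bump_sum_deriv(t - phase_h, config) / _deriv_max_abs(config)


def attach_fluorescence(
    table: MovieTable,
    config: Optional[GeneratorConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> MovieTable:
    """Fill each cell's per-frame reporter signal.

    yfp(t) = baseline + waveform(t; cell phase) * (1 + eps_t) with
    multiplicative frame noise eps_t ~ N(0, meas_noise_cv).
    """
    cfg = config or table.config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, table.colony_id, 1])
    for c in table.cells:
        if c.lengths.size != c.times.size:
            raise RuntimeError("lengths must be populated before fluorescence")
        w = expression_waveform(c.times, c.phase_h, cfg)
        noise = rng.normal(0.0, cfg.meas_noise_cv, size=w.shape) if cfg.meas_noise_cv else 0.0
        c.yfp = cfg.baseline_au + w * (1.0 + noise)
    return table


def attach_growth(table: MovieTable, config: Optional[GeneratorConfig] = None) -> MovieTable:
    """Re-integrate lengths with circadian growth-rate modulation.

    rate(t) = base_rate * (1 + depth * w_hat(t - growth_lag_h)) with w_hat the
    normalised expression-rate waveform, so log-length increments have the
    closed form  base_rate * [dt + depth * (W(t2-lag) - W(t1-lag)) / M]  where
    W is the expression waveform and M the derivative's max modulus.  Division
    lengths and daughters' birth lengths are propagated down the tree with the
    partition fractions drawn at growth time, so the forest stays consistent.
    With depth = 0 the table is returned unchanged.
    """
    cfg = config or table.config
    if cfg.growth_mod_depth == 0.0:
        return table
    depth = cfg.growth_mod_depth
    lag = cfg.growth_lag_h
    M = _deriv_max_abs(cfg)
    new_birth_len = {c.cell_id: c.birth_length_um for c in table.cells}
    for c in table.cells:  # creation order: parents precede children
        if c.yfp is None:
            raise RuntimeError("attach_fluorescence must run before attach_growth")
        b = new_birth_len[c.cell_id]
        c.birth_length_um = b

        def log_growth(t):
            t = np.asarray(t, dtype=float)
            lin = t - c.birth_time_h
            osc = (
                _bump_sum(t - lag - c.phase_h, cfg)
                - _bump_sum(np.array([c.birth_time_h - lag - c.phase_h]), cfg)[0]
            ) / M
            return c.base_rate_per_h * (lin + depth * osc)

        c.lengths = b * np.exp(log_growth(c.times))
        if c.division_time_h is not None:
            div_len = b * math.exp(float(log_growth(c.division_time_h)))
            for child in table.children(c.cell_id):
                new_birth_len[child.cell_id] = child.birth_fraction * div_len
    return table


def generate_movie(config: GeneratorConfig, colony_id: int = 0) -> MovieTable:
    """grow_tree -> attach_fluorescence -> attach_growth for one colony."""
    rng = np.random.default_rng([config.seed, colony_id])
    table = grow_tree(config, colony_id=colony_id, rng=rng)
    attach_fluorescence(table, config, rng=rng)
    attach_growth(table, config)
    return table


def generate_movies(config: GeneratorConfig) -> list[MovieTable]:
    """One MovieTable per colony, colony_id = 0..n_colonies-1."""
    return [generate_movie(config, colony_id=i) for i in range(config.n_colonies)]


def write_movie(table: MovieTable, csv_path, sidecar_path=None) -> None:
    """Tidy CSV plus a JSON sidecar holding the config snapshot and seed."""
    table.to_frame().to_csv(csv_path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {"colony_id": table.colony_id, "seed": table.seed,
                 "config": table.config.to_dict()},
                fh,
                indent=1,
            )
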