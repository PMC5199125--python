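"""Readers/writers, run configuration and the umbrella pipeline runner.

Conventions: times in hours, lengths in microns, fluorescence in arbitrary
units; movie tables are comma-separated UTF-8 CSV with a mandatory header
(columns colony_id, cell_id, parent_id, time_h, length_um, yfp_au;
parent_id -1 marks a root), with JSON sidecars for configs and manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lineages import CellRecord, GeneratorConfig, MovieTable, generate_movies, write_movie
from .pipeline import analyze_movie_peaks, pair_distances, rate_correlation

__all__ = ["MovieFormatError", "RunConfig", "read_movie_table", "run_pipeline"]

REQUIRED_COLUMNS = ["colony_id", "cell_id", "parent_id", "time_h", "length_um", "yfp_au"]

ALL_STAGES = ("generate", "traces", "peaks", "rates", "correlations")


class MovieFormatError(ValueError):
    pass


def _grid_step(times: np.ndarray) -> float:
    diffs = np.diff(np.unique(times))
    if diffs.size == 0:
        raise MovieFormatError("movie has a single frame")
    dt = float(diffs.min())
    if not np.allclose(np.round(diffs / dt) * dt, diffs, atol=1e-6):
        raise MovieFormatError("frame times do not lie on a uniform grid")
    return dt


def read_movie_table(path) -> list[MovieTable]:
    """Read a tidy movie CSV into one MovieTable per colony.

    Validates the header, the parent links (orphans are named), and the
    uniformity of each cell's frame grid.  Birth/division times are
    reconstructed as the midpoint between a mother's last frame and her
    daughters' first frame (the acquisition cadence bounds the error by one
    interval); generator-only fields (phase, base rate) are not recoverable
    and are set to NaN.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        raise MovieFormatError(f"{path} is not a movie table: {e}") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MovieFormatError(f"{path} is missing columns {missing}")
    if df.empty:
        raise MovieFormatError(f"{path} contains no rows")
    tables = []
    for colony_id, g in df.groupby("colony_id"):
        ids = set(g["cell_id"].unique())
        orphans = sorted(
            cid
            for cid, pid in g.groupby("cell_id")["parent_id"].first().items()
            if pid != -1 and pid not in ids
        )
        if orphans:
            raise MovieFormatError(
                f"colony {colony_id}: cells {orphans} reference absent parents"
            )
        dt = _grid_step(g["time_h"].to_numpy())
        cells = []
        by_cell = {cid: sub.sort_values("time_h") for cid, sub in g.groupby("cell_id")}
        children: dict[int, list[int]] = {}
        for cid, sub in by_cell.items():
            pid = int(sub["parent_id"].iloc[0])
            if pid != -1:
                children.setdefault(pid, []).append(int(cid))
        for cid, sub in sorted(by_cell.items()):
            t = sub["time_h"].to_numpy(dtype=float)
            steps = np.diff(t)
            if steps.size and not np.allclose(steps, dt, atol=1e-6):
                raise MovieFormatError(
                    f"colony {colony_id}: cell {cid} frames are not spaced by {dt}"
                )
            pid = int(sub["parent_id"].iloc[0])
            kids = children.get(int(cid), [])
            division = None
            if kids:
                first_kid_t = min(
                    by_cell[k]["time_h"].iloc[0] for k in kids
                )
                division = float((t[-1] + first_kid_t) / 2.0)
            cells.append(
                CellRecord(
                    cell_id=int(cid),
                    parent_id=None if pid == -1 else pid,
                    birth_time_h=float(t[0]),
                    division_time_h=division,
                    birth_length_um=float(sub["length_um"].iloc[0]),
                    phase_h=float("nan"),
                    base_rate_per_h=float("nan"),
                    birth_fraction=float("nan"),
                    times=t,
                    lengths=sub["length_um"].to_numpy(dtype=float),
                    yfp=sub["yfp_au"].to_numpy(dtype=float),
                )
            )
        # birth time of a non-root equals its parent's division time
        by_id = {c.cell_id: c for c in cells}
        for c in cells:
            if c.parent_id is not None:
                c.birth_time_h = by_id[c.parent_id].division_time_h
        cfg = GeneratorConfig(
            sample_interval_h=dt,
            duration_h=float(g["time_h"].max()) or dt,
        )
        tables.append(MovieTable(colony_id=int(colony_id), cells=cells, config=cfg, seed=-1))
    return tables


@dataclass
class RunConfig:
    """One reproducible end-to-end run of the pipeline."""

    preset: str = "WT_LOW"
    seed: int = 1
    duration_h: float = 120.0
    n_colonies: int = 2
    stages: tuple[str, ...] = ALL_STAGES
    lag_max_h: float = 48.0
    overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "seed": self.seed,
            "duration_h": self.duration_h,
            "n_colonies": self.n_colonies,
            "stages": list(self.stages),
            "lag_max_h": self.lag_max_h,
            "overrides": self.overrides,
        }

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig.from_preset(
            self.preset,
            seed=self.seed,
            duration_h=self.duration_h,
            n_colonies=self.n_colonies,
            **self.overrides,
        )


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the enabled stages and write all artifacts under ``out_dir``.

    A manifest (config, seed, config hash, package version) is written last;
    rerunning with the same config reproduces every file byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    tables = generate_movies(config.generator_config())
    if "generate" in config.stages:
        movie_dir = out / "movies"
        movie_dir.mkdir(exist_ok=True)
        for t in tables:
            write_movie(
                t,
                movie_dir / f"colony_{t.colony_id}.csv",
                movie_dir / f"colony_{t.colony_id}.json",
            )
    analyses = None
    if "traces" in config.stages or "peaks" in config.stages:
        analyses = [analyze_movie_peaks(t) for t in tables]
    if "traces" in config.stages:
        trace_dir = out / "traces"
        trace_dir.mkdir(exist_ok=True)
        pd.concat([a.fits_frame() for a in analyses], ignore_index=True).to_csv(
            trace_dir / "cosinor_fits.csv", index=False
        )
    if "peaks" in config.stages:
        peak_dir = out / "peaks"
        peak_dir.mkdir(exist_ok=True)
        pd.concat([a.peaks_frame() for a in analyses], ignore_index=True).to_csv(
            peak_dir / "peaks.csv", index=False
        )
        pd.concat([a.pairs_frame() for a in analyses], ignore_index=True).to_csv(
            peak_dir / "pairs.csv", index=False
        )
        within = pair_distances(analyses, same_window=True)
        allpairs = pair_distances(analyses)
        summary = {
            "n_pairs": int(allpairs.size),
            "n_within_window": int(within.size),
            "mean_within_window_distance_h": float(within.mean()) if within.size else None,
        }
        (peak_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    if "rates" in config.stages:
        from .growth import movie_rate_table

        rate_dir = out / "rates"
        rate_dir.mkdir(exist_ok=True)
        for t in tables:
            movie_rate_table(t).to_csv(
                rate_dir / f"rates_colony_{t.colony_id}.csv", index=False
            )
    if "correlations" in config.stages:
        corr_dir = out / "correlations"
        corr_dir.mkdir(exist_ok=True)
        res = rate_correlation(
            tables, x="expr_rate", y="elong_rate", lag_max_h=config.lag_max_h
        )
        pd.DataFrame(
            {
                "lag_h": res.lags,
                "R_mean": res.R,
                "R_sem": res.sem,
                "n_movies": res.n_movies,
            }
        ).to_csv(corr_dir / "expr_vs_elong_xcorr.csv", index=False)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "circatree_version": __version__,
        "stages": list(config.stages),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
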