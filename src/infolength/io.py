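"""CSV interchange for density snapshots, trajectories and derived series.

Snapshot CSV: columns ``x, p`` (one density).  Trajectory CSV: long format
``t, x, p`` ordered by (t asc, x asc), all snapshots on one shared uniform
grid.  Headers are required; everything is plain UTF-8.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid1D, GridPDF
from .info_geom import InfoSeries, PDFTrajectory

__all__ = [
    "write_snapshot_csv",
    "read_snapshot_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_info_csv",
    "write_thermo_csv",
]


def _grid_from_x(x: np.ndarray) -> Grid1D:
    dx = np.diff(x)
    if dx.min() <= 0 or (dx.max() - dx.min()) > 1e-9 * dx.mean():
        raise ValueError("x column is not a uniform increasing grid")
    return Grid1D(float(x[0]), float(x[-1]), len(x))


def write_snapshot_csv(pdf: GridPDF, path: str | Path) -> None:
    pd.DataFrame({"x": pdf.x, "p": pdf.p}).to_csv(path, index=False)


def read_snapshot_csv(path: str | Path) -> GridPDF:
    df = pd.read_csv(path)
    if not {"x", "p"}.issubset(df.columns):
        raise ValueError("snapshot CSV needs columns x, p")
    x = df["x"].to_numpy(dtype=float)
    return GridPDF(_grid_from_x(x), df["p"].to_numpy(dtype=float), normalize=True)


def write_trajectory_csv(traj: PDFTrajectory, path: str | Path) -> None:
    nt, nx = traj.densities.shape
    df = pd.DataFrame(
        {
            "t": np.repeat(traj.times, nx),
            "x": np.tile(traj.grid.x, nt),
            "p": traj.densities.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> PDFTrajectory:
    df = pd.read_csv(path)
    if not {"t", "x", "p"}.issubset(df.columns):
        raise ValueError("trajectory CSV needs columns t, x, p")
    df = df.sort_values(["t", "x"], kind="stable")
    times = np.unique(df["t"].to_numpy(dtype=float))
    x = np.unique(df["x"].to_numpy(dtype=float))
    grid = _grid_from_x(x)
    dens = df["p"].to_numpy(dtype=float).reshape(len(times), grid.n_points)
    return PDFTrajectory(times, grid, dens)


def write_info_csv(series: InfoSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t": series.times,
            "Gamma": series.gamma,
            "E": series.E,
            "L": series.L if series.L is not None else np.nan,
        }
    ).to_csv(path, index=False)


def write_thermo_csv(series, path: str | Path) -> None:
    cols = {
        "t": series.times,
        "S": series.S,
        "Sdot": series.Sdot,
        "ST_dot": series.ST_dot,
        "Sm_dot": series.Sm_dot,
        "Qdot": series.Qdot,
        "Wdot": series.Wdot,
        "U": series.U,
    }
    for name in ("F", "WD_dot", "K_s", "c_fluct"):
        val = getattr(series, name)
        if val is not None:
            cols[name] = val
    pd.DataFrame(cols).to_csv(path, index=False)
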