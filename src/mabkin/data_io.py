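"""Measurement tables, dense interpolation and discrete derivatives.

Batch-culture concentration data come as sparse offline samples (here 7
time points over a 147 h batch, each a mean over replicate experiments with
a standard deviation).  Parameter estimation needs values between samples,
so measured variables are densified with a shape-preserving piecewise-cubic
Hermite interpolant (continuous value and first derivative, no overshoot —
important because substrates that hit zero must not dip negative, which
would break the Monod rate factors).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .model import ExperimentDesign, STATE_NAMES

#: The antibody column of measurement CSVs is on the 1e-4 mM scale.
MAB_SCALE = 1e-4
#: Variables of the bundled measurement table (glutamate and ammonia are
#: not measured).
MEASURED_VARIABLES: tuple[str, ...] = (
    "GLC", "GLN", "ASN", "ASP", "LAC", "ALA", "PRO", "MAb", "BM", "X", "Xd",
)


class MeasurementFormatError(ValueError):
    """Raised for malformed measurement CSVs, naming the offending cell."""


@dataclass(frozen=True)
class MeasurementTable:
    """Sparse timed concentration means and standard deviations.

    All values are in model units (metabolites mM — including the antibody —
    cells in 1e6 cells/mL).
    """

    times: np.ndarray
    variables: tuple[str, ...]
    mean: np.ndarray  # times x variables
    sd: np.ndarray    # times x variables, >= 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise MeasurementFormatError("times must be strictly increasing")
        if m.shape != (t.size, len(self.variables)) or s.shape != m.shape:
            raise MeasurementFormatError("mean/sd shape must be times x variables")
        unknown = set(self.variables) - set(STATE_NAMES)
        if unknown:
            raise MeasurementFormatError(f"unknown variable name(s): {sorted(unknown)}")
        if np.any(m < 0):
            k, j = np.argwhere(m < 0)[0]
            raise MeasurementFormatError(
                f"negative mean for {self.variables[j]} at t={t[k]} h"
            )
        if np.any(s < 0):
            k, j = np.argwhere(s < 0)[0]
            raise MeasurementFormatError(
                f"negative sd for {self.variables[j]} at t={t[k]} h"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sd", s)

    def column(self, name: str) -> np.ndarray:
        return self.mean[:, self.variables.index(name)]

    def sd_column(self, name: str) -> np.ndarray:
        return self.sd[:, self.variables.index(name)]


def load_measurements(source: str | Path) -> MeasurementTable:
    """Read a measurement CSV, or ``"bundled"`` for the packaged batch data.

    Expected layout: ``time_h`` column, then ``var, var_sd`` pairs.  The
    antibody columns are interpreted on the 1e-4 mM scale and converted to mM.
    """
    if source == "bundled":
        from importlib.resources import files

        with files("mabkin.data").joinpath("table3.csv").open() as fh:
            df = pd.read_csv(fh, float_precision="round_trip")
    else:
        p = Path(source)
        try:
            df = pd.read_csv(p, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise MeasurementFormatError(f"{p}: empty file") from None
    if "time_h" not in df.columns:
        raise MeasurementFormatError("missing 'time_h' column")
    var_cols = [c for c in df.columns if c != "time_h" and not c.endswith("_sd")]
    for v in var_cols:
        if f"{v}_sd" not in df.columns:
            raise MeasurementFormatError(f"missing sd column for variable {v!r}")
    mean = df[var_cols].to_numpy(dtype=float)
    sd = df[[f"{v}_sd" for v in var_cols]].to_numpy(dtype=float)
    if "MAb" in var_cols:
        j = var_cols.index("MAb")
        mean[:, j] *= MAB_SCALE
        sd[:, j] *= MAB_SCALE
    return MeasurementTable(
        times=df["time_h"].to_numpy(dtype=float),
        variables=tuple(var_cols),
        mean=mean,
        sd=sd,
    )


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write a table in the CSV dialect of :func:`load_measurements`.

    Values are printed with 17 significant digits so a round trip through
    the file reproduces them (the antibody rescaling to the 1e-4 mM column
    scale can move the last bit).
    """
    cols: dict[str, np.ndarray] = {"time_h": table.times}
    for j, v in enumerate(table.variables):
        scale = 1.0 / MAB_SCALE if v == "MAb" else 1.0
        cols[v] = table.mean[:, j] * scale
        cols[f"{v}_sd"] = table.sd[:, j] * scale
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class InterpolatedTrajectory:
    """Dense clamped cubic-Hermite interpolants of the measured variables."""

    grid: np.ndarray
    variables: tuple[str, ...]
    values: np.ndarray  # grid x variables, >= 0
    source: MeasurementTable

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variables.index(name)]


def interpolate(table: MeasurementTable, design: ExperimentDesign) -> InterpolatedTrajectory:
    """Densify a measurement table on the grid 0, Ts, ..., t_final.

    Uses the monotone shape-preserving piecewise-cubic Hermite rule (PCHIP):
    the interpolant passes exactly through every measured mean, has a
    continuous first derivative, and cannot overshoot the data — so
    variables measured at zero stay at zero.  Values are additionally
    clamped at zero from below.  No extrapolation: the grid must lie within
    the measured time range.
    """
    if table.times.size < 2:
        raise MeasurementFormatError("need at least 2 time points to interpolate")
    grid = design.grid
    if grid[0] < table.times[0] or grid[-1] > table.times[-1] + 1e-9:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] h extends beyond the measured range "
            f"[{table.times[0]}, {table.times[-1]}] h; extrapolation is not supported"
        )
    values = np.empty((grid.size, len(table.variables)))
    for j in range(len(table.variables)):
        values[:, j] = PchipInterpolator(table.times, table.mean[:, j])(grid)
    # replace grid points that coincide with knots by the exact means
    for row, g in enumerate(table.times):
        k = int(np.argmin(np.abs(grid - g)))
        if abs(grid[k] - g) < 1e-9:
            values[k, :] = table.mean[row, :]
    return InterpolatedTrajectory(
        grid=grid, variables=table.variables, values=np.maximum(values, 0.0), source=table
    )


def finite_difference(traj: InterpolatedTrajectory) -> np.ndarray:
    """Forward-difference derivative series on the dense grid.

    d[k] = (v[k+1] - v[k]) / Ts, with the last grid point carrying the
    backward difference.  The truncation error is proportional to Ts.
    """
    v = traj.values
    if v.shape[0] < 2:
        raise ValueError("need at least 2 grid points")
    ts = np.diff(traj.grid)[:, None]
    d = np.empty_like(v)
    d[:-1] = np.diff(v, axis=0) / ts
    d[-1] = d[-2] if v.shape[0] == 2 else (v[-1] - v[-2]) / ts[-1]
    return d


def write_trajectory(traj: InterpolatedTrajectory, path: str | Path) -> None:
    """Export a dense trajectory to CSV (model units, no rescaling)."""
    df = pd.DataFrame(traj.values, columns=list(traj.variables))
    df.insert(0, "time_h", traj.grid)
    df.to_csv(path, index=False)
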