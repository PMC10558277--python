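"""Thermometry-style validation analytics.

Mirrors how MR thermometry is used to validate a simulated temperature
field: temperature is sampled along line profiles and compared point by
point (mean/max absolute difference, Pearson correlation), probe-point
time series are extracted from a checkpointed trajectory, and synthetic
noisy thermometry frames (Gaussian noise scaled by an SNR, one frame per
acquisition interval) stand in for scanner data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .geometry import StructuredMesh

__all__ = [
    "LineProfile",
    "ComparisonReport",
    "line_profile",
    "compare_profiles",
    "synthesize_thermometry",
    "probe_timeseries",
    "DEFAULT_SNR",
    "SIGMA_REF",
]

# noise calibration: sigma = SIGMA_REF / snr; the defaults give a 1 °C
# standard deviation, typical of PRF thermometry at moderate SNR
DEFAULT_SNR = 40.0
SIGMA_REF = 40.0


@dataclass
class LineProfile:
    """Field values sampled along a straight segment.

    positions_mm : distances along the segment (mm), strictly increasing.
    values : sampled field values (°C for temperature fields).
    start, end : segment endpoints (m).
    interpolation : 'multilinear' or 'nearest'.
    """

    positions_mm: np.ndarray
    values: np.ndarray
    start: tuple[float, ...]
    end: tuple[float, ...]
    interpolation: str = "multilinear"

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_mm.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if not np.all(np.diff(self.positions_mm) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class ComparisonReport:
    """Profile-vs-profile statistics.

    mean_abs_diff, max_abs_diff : °C; pearson_r with two-sided p_value;
    n : number of samples compared.
    """

    mean_abs_diff: float
    max_abs_diff: float
    pearson_r: float
    p_value: float
    n: int


def line_profile(
    field: np.ndarray,
    mesh: StructuredMesh,
    start,
    end,
    n: int,
    mode: str = "multilinear",
) -> LineProfile:
    """Sample a cell field at ``n`` even points along a segment.

    ``multilinear`` interpolates between cell centers (coordinates are
    clamped to the cell-center range, so samples in the outer half-cell
    take the nearest center value along that axis); ``nearest`` takes the
    containing cell's value.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if start.shape != (mesh.dim,) or end.shape != (mesh.dim,):
        raise ValueError(f"endpoints must have {mesh.dim} coordinates")
    for p in (start, end):
        if np.any(p < -1e-12) or np.any(p > np.asarray(mesh.extents) + 1e-12):
            raise ValueError("profile segment exits the domain")
    if n < 2:
        raise ValueError("need at least 2 sample points")
    if mode not in ("multilinear", "nearest"):
        raise ValueError("mode must be 'multilinear' or 'nearest'")

    t = np.linspace(0.0, 1.0, n)
    pts = start + t[:, None] * (end - start)
    values = _interpolate(field, mesh, pts, mode)
    dist_mm = t * np.linalg.norm(end - start) * 1e3
    return LineProfile(
        positions_mm=dist_mm, values=values,
        start=tuple(start), end=tuple(end), interpolation=mode,
    )


def _interpolate(field, mesh: StructuredMesh, pts: np.ndarray, mode: str):
    axes = [
        (np.arange(c) + 0.5) * h for c, h in zip(mesh.shape, mesh.spacing)
    ]
    grid = np.asarray(field, dtype=float).reshape(mesh.shape)
    method = "linear" if mode == "multilinear" else "nearest"
    # clamp into the cell-center hull to avoid extrapolation
    clamped = np.column_stack([
        np.clip(pts[:, a], axes[a][0], axes[a][-1]) for a in range(mesh.dim)
    ])
    interp = RegularGridInterpolator(axes, grid, method=method)
    return interp(clamped)


def compare_profiles(sim: LineProfile, meas: LineProfile) -> ComparisonReport:
    """Pointwise comparison of a simulated and a measured profile."""
    if len(sim.positions_mm) != len(meas.positions_mm) or not np.allclose(
        sim.positions_mm, meas.positions_mm
    ):
        raise ValueError("profiles must share the same sample positions")
    d = sim.values - meas.values
    if np.std(sim.values) == 0 or np.std(meas.values) == 0:
        raise ValueError("correlation undefined for zero-variance profile")
    r, p = stats.pearsonr(sim.values, meas.values)
    return ComparisonReport(
        mean_abs_diff=float(np.mean(np.abs(d))),
        max_abs_diff=float(np.max(np.abs(d))),
        pearson_r=float(r),
        p_value=float(p),
        n=len(d),
    )


def synthesize_thermometry(
    trajectory,
    snr: float = DEFAULT_SNR,
    frame_dt: float = 22.3,
    seed: int | None = None,
    sigma_ref: float = SIGMA_REF,
):
    """Noisy thermometry frames from a checkpointed temperature trajectory.

    One frame is produced per ``frame_dt`` seconds (nearest checkpoint in
    time) with i.i.d. zero-mean Gaussian noise of standard deviation
    ``sigma_ref / snr`` added, emulating PRF temperature-map noise whose
    magnitude is set by the image SNR.

    Returns ``(frame_times, frames, sigma)``; frames have one row per
    frame over the flat cell field.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    times = np.array([s.time for s in trajectory])
    t_frames = np.arange(0.0, times[-1] + 1e-9, frame_dt)
    idx = np.abs(times[None, :] - t_frames[:, None]).argmin(axis=1)
    fields = np.stack([trajectory[i].thermal.u for i in idx])
    sigma = sigma_ref / snr
    rng = np.random.default_rng(seed)
    frames = fields + rng.normal(0.0, sigma, size=fields.shape)
    return t_frames, frames, sigma


def probe_timeseries(trajectory, points, mesh: StructuredMesh) -> pd.DataFrame:
    """Temperature time series at probe points (nearest cell per point).

    Returns a DataFrame with a ``time_s`` column and one column per probe
    named by its coordinates.
    """
    cols = {"time_s": [s.time for s in trajectory]}
    for pt in points:
        p = np.asarray(pt, dtype=float)
        if p.shape != (mesh.dim,):
            raise ValueError(f"probe point must have {mesh.dim} coordinates")
        if np.any(p < 0) or np.any(p > np.asarray(mesh.extents)):
            raise ValueError(f"probe point {pt} outside the domain")
        multi = tuple(
            min(int(p[a] / mesh.spacing[a]), mesh.shape[a] - 1)
            for a in range(mesh.dim)
        )
        cell = mesh.cell_index(multi)
        name = "u_at_" + "_".join(f"{x:g}" for x in p)
        while name in cols:  # duplicate probes get their own column
            name += "'"
        cols[name] = [float(s.thermal.u[cell]) for s in trajectory]
    return pd.DataFrame(cols)
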