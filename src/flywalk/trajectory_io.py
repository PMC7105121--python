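"""Trajectory tables, arena configuration and the tracking-style smoother.

A trajectory is a uniformly sampled (default 30 Hz) table of arena-centered
centroid positions (mm) and body orientation (degrees, CCW from +x). The
smoother reproduces the two-pass LOESS scheme used for video-tracked flies:
coarse windows (1 s position, 1.3 s orientation) everywhere, with a fine
re-smooth (0.2 s / 0.3 s) wherever the coarse fit moves the centroid more
than 0.0037 mm from the raw track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ArenaConfig",
    "Trajectory",
    "SEGMENT_COLUMNS",
    "STATES",
    "SCENARIOS",
    "read_trajectory",
    "write_trajectory",
    "read_segments",
    "write_segments",
    "smooth_trajectory",
    "load_config",
    "save_config",
    "ellipse_area",
]

STATES = ("boundary", "stop", "sharp_turn", "curved_walk")
SCENARIOS = ("before", "during_in", "during_out")

#: canonical segment-table schema (see write_segments)
SEGMENT_COLUMNS = [
    "state",
    "start_frame",
    "end_frame",
    "peak_frame",
    "scenario",
    "mean_speed_mm_s",
    "total_curv_deg",
    "mean_curv_deg_frame",
    "duration_s",
]


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory table violates the format contract."""


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry, light profile and timing of the circular-arena assay.

    Lengths in mm, times in seconds. The light-zone is at full intensity out
    to ``light_full_mm``, ramps linearly to zero at ``light_zero_mm`` and the
    behavioural "light border" used for scenario splits and border choice
    sits at ``border_norm`` of the arena radius (12 mm for the defaults).
    """

    arena_radius_mm: float = 40.0
    light_radius_mm: float = 12.5
    light_full_mm: float = 10.0
    light_zero_mm: float = 13.0
    border_norm: float = 0.3
    fps: float = 30.0
    light_on_s: float = 180.0
    total_s: float = 360.0
    stop_speed_mm_s: float = 0.5
    boundary_margin_mm: float = 1.5
    #: max body rotation rate used by the tracker's head/tail sanity check
    max_turn_deg_frame: float = 120.0

    def __post_init__(self) -> None:
        for name in ("arena_radius_mm", "light_radius_mm", "light_full_mm",
                     "light_zero_mm", "fps", "boundary_margin_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.light_full_mm <= self.light_zero_mm <= self.arena_radius_mm):
            raise ValueError("require light_full_mm <= light_zero_mm <= arena_radius_mm")
        if not 0.0 < self.border_norm < 1.0:
            raise ValueError("border_norm must lie in (0, 1)")
        if not self.light_on_s < self.total_s:
            raise ValueError("light_on_s must precede total_s")

    @property
    def border_radius_mm(self) -> float:
        """Radius of the light border (normalized location ``border_norm``)."""
        return self.border_norm * self.arena_radius_mm

    @property
    def n_frames(self) -> int:
        return int(round(self.total_s * self.fps))

    @property
    def max_turn_deg_s(self) -> float:
        """Angular-speed cap expressed per second instead of per frame."""
        return self.max_turn_deg_frame * self.fps


def ellipse_area(semi_major_mm: float, semi_minor_mm: float) -> float:
    """Area of an ellipse; the tracker's minimum detectable fly is (1, 0.5)."""
    if semi_major_mm <= 0 or semi_minor_mm <= 0:
        raise ValueError("semi-axes must be positive")
    return float(np.pi * semi_major_mm * semi_minor_mm)


@dataclass
class Trajectory:
    """One fly's track: time (s), centroid (mm) and orientation (deg)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = np.mod(np.asarray(self.theta, dtype=float), 360.0)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not all(len(a) == n for a in (self.x, self.y, self.theta, self.valid)):
            raise TrajectoryFormatError("trajectory columns have unequal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def r(self) -> np.ndarray:
        """Radial distance from arena center, mm."""
        return np.hypot(self.x, self.y)

    def validate(self, config: ArenaConfig, tol_mm: float = 0.5) -> None:
        """Check uniform sampling and arena containment."""
        if len(self) >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / config.fps, rtol=0, atol=1e-6):
                raise TrajectoryFormatError("non-uniform frame spacing")
        if np.any(self.r > config.arena_radius_mm + tol_mm):
            raise TrajectoryFormatError(
                f"point outside the {config.arena_radius_mm} mm arena")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self)),
            "t": self.t,
            "x_mm": self.x,
            "y_mm": self.y,
            "theta_deg": self.theta,
            "valid": self.valid.astype(int),
        })

    def copy(self) -> "Trajectory":
        return Trajectory(self.t.copy(), self.x.copy(), self.y.copy(),
                          self.theta.copy(), self.valid.copy())


def read_trajectory(path: str | Path, config: ArenaConfig) -> Trajectory:
    """Read a trajectory CSV (columns frame, x, y, theta[, t, valid]).

    Gaps in the frame index are filled by linear interpolation and the
    interpolated frames flagged invalid, mirroring how untrackable video
    frames were handled upstream.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    alias = {"x": ("x", "x_mm"), "y": ("y", "y_mm"), "theta": ("theta", "theta_deg"),
             "frame": ("frame",)}
    resolved = {}
    for key, names in alias.items():
        for nm in names:
            if nm in cols:
                resolved[key] = cols[nm]
                break
        else:
            raise TrajectoryFormatError(f"missing required column {names[0]!r}")
    frames = df[resolved["frame"]].to_numpy(dtype=int)
    if len(frames) == 0:
        raise TrajectoryFormatError("empty trajectory file")
    if np.any(np.diff(frames) <= 0):
        raise TrajectoryFormatError("frame index must be strictly increasing")

    full = np.arange(frames[0], frames[-1] + 1)
    x = np.interp(full, frames, df[resolved["x"]].to_numpy(dtype=float))
    y = np.interp(full, frames, df[resolved["y"]].to_numpy(dtype=float))
    # interpolate orientation on the unwrapped angle to avoid 360-deg jumps
    th_unwrap = np.degrees(np.unwrap(np.radians(df[resolved["theta"]].to_numpy(dtype=float))))
    theta = np.interp(full, frames, th_unwrap)
    valid = np.isin(full, frames)
    if "valid" in cols:
        valid = valid & np.interp(full, frames, df[cols["valid"]].to_numpy(dtype=float)).astype(bool)
    t = (full - full[0]) / config.fps
    traj = Trajectory(t=t, x=x, y=y, theta=theta, valid=valid)
    traj.validate(config)
    return traj


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns and c != "peak_frame"]
    if missing:
        raise TrajectoryFormatError(f"segment table missing columns: {missing}")
    bad = set(df["state"].unique()) - set(STATES)
    if bad:
        raise TrajectoryFormatError(f"unknown state labels: {sorted(bad)}")
    return df


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SEGMENT_COLUMNS if c in segments.columns]
    segments[cols].to_csv(path, index=False)


def _loess(values: np.ndarray, window_frames: int) -> np.ndarray:
    """Local-linear LOESS with a window of ``window_frames`` nearest points."""
    n = len(values)
    frac = min(1.0, max(window_frames, 3) / n)
    idx = np.arange(n, dtype=float)
    return lowess(values, idx, frac=frac, it=0, return_sorted=False)


def smooth_trajectory(traj: Trajectory, config: ArenaConfig,
                      pos_window_s: float = 1.0,
                      theta_window_s: float = 1.3,
                      fine_pos_window_s: float = 0.2,
                      fine_theta_window_s: float = 0.3,
                      fallback_tol_mm: float = 0.0037) -> Trajectory:
    """Two-pass LOESS smoothing of centroid and orientation.

    Orientation is unwrapped before smoothing and re-wrapped after. Frames
    where the coarse positional fit deviates from the raw centroid by more
    than ``fallback_tol_mm`` fall back to the fine windows (both position and
    orientation, keeping the two channels temporally consistent).
    """
    n = len(traj)
    max_win = int(round(max(pos_window_s, theta_window_s) * config.fps))
    if n < max(max_win, 2):
        raise ValueError(f"trajectory too short to smooth ({n} frames < {max_win})")

    wpos = int(round(pos_window_s * config.fps))
    wth = int(round(theta_window_s * config.fps))
    xs, ys = _loess(traj.x, wpos), _loess(traj.y, wpos)
    th_unwrap = np.degrees(np.unwrap(np.radians(traj.theta)))
    ths = _loess(th_unwrap, wth)

    err = np.hypot(xs - traj.x, ys - traj.y)
    bad = err > fallback_tol_mm
    if np.any(bad):
        wfp = int(round(fine_pos_window_s * config.fps))
        wft = int(round(fine_theta_window_s * config.fps))
        xf, yf = _loess(traj.x, wfp), _loess(traj.y, wfp)
        thf = _loess(th_unwrap, wft)
        xs[bad], ys[bad], ths[bad] = xf[bad], yf[bad], thf[bad]

    return Trajectory(t=traj.t.copy(), x=xs, y=ys, theta=np.mod(ths, 360.0),
                      valid=traj.valid.copy())


def load_config(path: str | Path) -> ArenaConfig:
    """Read an ArenaConfig from YAML (unknown keys rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(ArenaConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ArenaConfig(**data)


def save_config(config: ArenaConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: getattr(config, k) for k in ArenaConfig.__dataclass_fields__}, fh)
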