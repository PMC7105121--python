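"""Per-frame kinematic descriptors of a fly's track.

Fly-centric frame: thrust T (mm/s, along the body axis), slip S (mm/s,
perpendicular) and yaw Y (deg/frame, change in body orientation). World
frame: speed s (mm/s), movement angle phi (deg, body orientation minus
direction of travel) and signed path curvature k (deg/frame) defined as the
frame-to-frame rotation of the path's normal vector. Counter-clockwise
turning is positive for both k and Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import ArenaConfig, Trajectory

__all__ = ["KinematicSeries", "compute_kinematics", "compute_curvature",
           "yaw_contribution", "wrap_angle"]

#: speeds below this (mm/s) make the movement direction undefined
SPEED_EPS = 1e-6


def wrap_angle(a):
    """Wrap angle(s) in degrees to (-180, 180]."""
    return -np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) + 180.0


@dataclass
class KinematicSeries:
    """Per-frame kinematics; index t refers to the step from frame t to t+1.

    The final frame (and, for curvature, the first and final steps) has no
    defined value and carries NaN. ``moving`` flags frames whose speed
    exceeds ``SPEED_EPS`` so direction-dependent quantities are defined.
    """

    s: np.ndarray          # speed, mm/s
    phi: np.ndarray        # movement angle, deg in (-180, 180]
    thrust: np.ndarray     # mm/s
    slip: np.ndarray       # mm/s
    yaw: np.ndarray        # deg/frame
    curvature: np.ndarray  # signed, deg/frame; NaN where undefined
    moving: np.ndarray     # bool

    def __len__(self) -> int:
        return len(self.s)

    @property
    def curvature_filled(self) -> np.ndarray:
        """Curvature with undefined frames as 0 (for cumulative sums)."""
        return np.nan_to_num(self.curvature, nan=0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s": self.s, "phi": self.phi, "thrust": self.thrust,
            "slip": self.slip, "yaw": self.yaw, "curvature": self.curvature,
        })


def compute_kinematics(traj: Trajectory, config: ArenaConfig) -> KinematicSeries:
    """Compute speed, movement angle, thrust/slip, yaw and curvature."""
    n = len(traj)
    if n < 3:
        raise ValueError("need at least 3 frames for kinematics")
    dt = 1.0 / config.fps
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    step = np.hypot(dx, dy)                      # mm per frame
    s = np.full(n, np.nan)
    s[:-1] = step / dt
    moving = np.zeros(n, dtype=bool)
    moving[:-1] = s[:-1] > SPEED_EPS

    move_dir = np.full(n, np.nan)
    move_dir[:-1] = np.degrees(np.arctan2(dy, dx))
    phi = np.full(n, np.nan)
    phi[moving] = wrap_angle(traj.theta[moving] - move_dir[moving])

    thrust = np.full(n, np.nan)
    slip = np.full(n, np.nan)
    thrust[moving] = s[moving] * np.cos(np.radians(phi[moving]))
    slip[moving] = s[moving] * np.sin(np.radians(phi[moving]))
    # a stopped fly exerts no thrust/slip; keep them defined (0) when s ~ 0
    stopped = ~moving
    stopped[-1] = False
    thrust[stopped] = 0.0
    slip[stopped] = 0.0

    yaw = np.full(n, np.nan)
    th_unwrap = np.degrees(np.unwrap(np.radians(traj.theta)))
    yaw[:-1] = wrap_angle(np.diff(th_unwrap))

    curvature = compute_curvature(traj, config)
    return KinematicSeries(s=s, phi=phi, thrust=thrust, slip=slip, yaw=yaw,
                           curvature=curvature, moving=moving)


def compute_curvature(traj: Trajectory, config: ArenaConfig) -> np.ndarray:
    """Signed path curvature (deg/frame) from the normal-vector rotation.

    The tangent direction at frame t averages the unit displacements of the
    two adjacent steps; the normal is its left (CCW) perpendicular, and the
    curvature at step t is the wrapped rotation of the normal between
    consecutive frames, via atan2 of the 2-D cross/dot product. Frames
    adjoining a zero-speed step are undefined (NaN).
    """
    n = len(traj)
    if n < 3:
        raise ValueError("need at least 3 frames for curvature")
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    step = np.hypot(dx, dy)
    ok = step > SPEED_EPS * (1.0 / config.fps)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(ok, dx / step, np.nan)
        uy = np.where(ok, dy / step, np.nan)
    # normal at interior frame t from steps t-1 and t (left perpendicular)
    nx = -(uy[:-1] + uy[1:])
    ny = ux[:-1] + ux[1:]
    norm = np.hypot(nx, ny)
    with np.errstate(invalid="ignore", divide="ignore"):
        nx, ny = nx / norm, ny / norm
    curvature = np.full(n, np.nan)
    # rotation of the normal between interior frames t and t+1 -> step t
    cross = nx[:-1] * ny[1:] - ny[:-1] * nx[1:]
    dot = nx[:-1] * nx[1:] + ny[:-1] * ny[1:]
    curvature[1:-2] = np.degrees(np.arctan2(cross, dot))
    return curvature


def yaw_contribution(segments: pd.DataFrame, kin: KinematicSeries,
                     n_bins: int = 10) -> pd.DataFrame:
    """Yaw's share of reorientation across the normalized span of sharp turns.

    For each sharp-turn segment the yaw and curvature series are binned onto
    ``n_bins`` normalized-duration bins; p = mean yaw / mean curvature per
    bin, pooled over turns, and 1 - p is the slip-angle contribution. Bins
    whose pooled mean curvature is ~0 are flagged undefined (NaN).
    """
    turns = segments[segments["state"] == "sharp_turn"]
    if len(turns) == 0:
        raise ValueError("no sharp-turn segments")
    yaw_sum = np.zeros(n_bins)
    curv_sum = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for _, seg in turns.iterrows():
        f0, f1 = int(seg.start_frame), int(seg.end_frame)
        frames = np.arange(f0, f1 + 1)
        span = max(len(frames) - 1, 1)
        bins = np.minimum((n_bins * (frames - f0) / (span + 1)).astype(int), n_bins - 1)
        y = kin.yaw[frames]
        k = kin.curvature[frames]
        good = ~(np.isnan(y) | np.isnan(k))
        np.add.at(yaw_sum, bins[good], y[good])
        np.add.at(curv_sum, bins[good], k[good])
        np.add.at(counts, bins[good], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_yaw = yaw_sum / counts
        mean_curv = curv_sum / counts
        p = np.where(np.abs(mean_curv) > 1e-9, mean_yaw / mean_curv, np.nan)
    return pd.DataFrame({
        "bin": np.arange(n_bins),
        "t_norm": (np.arange(n_bins) + 0.5) / n_bins,
        "p_yaw": p,
        "p_slip": 1.0 - p,
        "n_frames": counts.astype(int),
    })
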