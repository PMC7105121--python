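"""Cohort-level locomotor metrics: attraction, radial occupancy, turn density.

All radial quantities use the radius normalized to the arena radius; the
light border sits at 0.3 for the default geometry. Scenario splits follow
the before / after-first-entry convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import _scenario_frames
from .trajectory_io import ArenaConfig, Trajectory

__all__ = ["attraction_index", "radial_occupancy", "radial_turn_density",
           "scenario_masks"]


def scenario_masks(traj: Trajectory, config: ArenaConfig) -> dict[str, np.ndarray]:
    """Frame masks for 'before' (pre first entry) and 'after' (post)."""
    scen = _scenario_frames(traj, config)
    before = scen == "before"
    return {"before": before, "after": ~before}


def attraction_index(traj: Trajectory, config: ArenaConfig,
                     scenario: str = "after") -> float:
    """Fraction of scenario time spent inside the light border."""
    masks = scenario_masks(traj, config)
    if scenario not in masks:
        raise ValueError("scenario must be 'before' or 'after'")
    mask = masks[scenario]
    if not mask.any():
        raise ValueError(f"no frames in scenario {scenario!r}")
    inside = traj.r[mask] < config.border_radius_mm
    return float(inside.mean())


def radial_occupancy(trajs: list[Trajectory], config: ArenaConfig,
                     scenario: str | None = None,
                     bin_width: float = 0.1) -> np.ndarray:
    """Cohort radial-position histogram (the 'average fly').

    Each fly's normalized-radius histogram is computed first and the per-fly
    pmfs averaged, so every fly carries equal weight. 10 bins of width 0.1
    by default; the outermost bin is closed at 1.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    per_fly = []
    for traj in trajs:
        r = traj.r / config.arena_radius_mm
        if scenario is not None:
            mask = scenario_masks(traj, config)[scenario]
            r = r[mask]
        if len(r) == 0:
            continue
        hist, _ = np.histogram(np.clip(r, 0, 1 - 1e-12), bins=edges)
        per_fly.append(hist / hist.sum())
    if not per_fly:
        raise ValueError("no frames in the requested scenario")
    pmf = np.mean(per_fly, axis=0)
    return pmf / pmf.sum()


def radial_turn_density(segments: pd.DataFrame, traj: Trajectory,
                        config: ArenaConfig, bin_width: float = 0.1,
                        scenario: str | None = None) -> np.ndarray:
    """Area-corrected, normalized density of sharp-turn locations.

    f_R(r_k) = P_R(r_k) / (pi (r_{k+1}^2 - r_k^2)), renormalized to sum to 1,
    with turn locations taken at the peak-curvature frame.
    """
    turns = segments[segments["state"] == "sharp_turn"]
    if scenario is not None:
        if scenario == "before":
            turns = turns[turns["scenario"] == "before"]
        else:
            turns = turns[turns["scenario"] != "before"]
    if len(turns) == 0:
        raise ValueError("no sharp turns")
    frames = turns["peak_frame"].to_numpy(dtype=int)
    r = traj.r[frames] / config.arena_radius_mm
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    hist, _ = np.histogram(np.clip(r, 0, 1 - 1e-12), bins=edges)
    pmf = hist / hist.sum()
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    f = pmf / areas
    return f / f.sum()
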