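"""Per-state, per-scenario joint densities that drive the generative model.

Each of the four locomotor states is summarized by a low-dimensional joint
pdf fitted from segment tables: stops and sharp turns by (duration, total
curvature), curved walks by (speed, duration, mean curvature) and the
boundary state by (duration, arc angle). Densities are Gaussian-kernel
KDEs with plug-in (Scott) bandwidth; sampling draws a data point and adds
kernel noise, with rejection at the support bounds (durations > 0,
speeds >= 0). Total curvature is kept signed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .trajectory_io import SCENARIOS

__all__ = ["StateKDE", "StateDistributions", "fit_state_distributions",
           "sample_state", "save_distributions", "load_distributions",
           "STATE_FEATURES"]

#: joint-pdf feature columns per state, in sampling order
STATE_FEATURES = {
    "stop": ("duration_s", "total_curv_deg"),
    "sharp_turn": ("duration_s", "total_curv_deg"),
    "curved_walk": ("mean_speed_mm_s", "duration_s", "mean_curv_deg_frame"),
    "boundary": ("duration_s", "total_curv_deg"),  # total = arc angle for boundary
}

#: per-dimension lower bounds of the support (None = unbounded); durations
#: cannot reach 0 exactly (a segment is at least one frame long)
_SUPPORT_LO = {
    "stop": (1e-6, None),
    "sharp_turn": (1e-6, None),
    "curved_walk": (0.0, 1e-6, None),
    "boundary": (1e-6, None),
}

ARCHIVE_VERSION = 1

#: structurally empty cells: the wall lies outside the light zone, so a
#: boundary excursion can never carry the during-inside scenario
OPTIONAL_CELLS = {("during_in", "boundary")}


class StateKDE:
    """Sampleable multivariate Gaussian KDE with truncated support.

    Thin wrapper over :class:`scipy.stats.gaussian_kde` that remembers the
    training points and rejects samples violating the per-dimension lower
    bounds.
    """

    def __init__(self, data: np.ndarray, lower: tuple | None = None,
                 bw_method: str | float = "scott") -> None:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.shape[0] < data.shape[1]:
            raise ValueError("need more observations than dimensions")
        self.data = data
        self.lower = lower if lower is not None else (None,) * data.shape[1]
        self._degenerate = bool(np.linalg.matrix_rank(np.cov(data.T)) < data.shape[1]) \
            if data.shape[0] > 1 else True
        if self._degenerate:
            # all-identical (or rank-deficient) observations: fall back to a
            # point-cloud with a tiny isotropic kernel
            scale = max(np.abs(data).max(), 1.0)
            self._eps = 1e-6 * scale
            self._kde = None
        else:
            self._kde = gaussian_kde(data.T, bw_method=bw_method)

    @property
    def d(self) -> int:
        return self.data.shape[1]

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def bandwidth(self) -> np.ndarray:
        """Kernel covariance matrix."""
        if self._kde is None:
            return np.eye(self.d) * self._eps ** 2
        return np.asarray(self._kde.covariance)

    def pdf(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._kde is None:
            # near-delta density; report kernel value of the tiny Gaussian
            diff = points - self.data.mean(axis=0)
            q = np.sum(diff ** 2, axis=1) / self._eps ** 2
            norm = (2 * np.pi * self._eps ** 2) ** (-self.d / 2)
            return norm * np.exp(-q / 2)
        return self._kde(points.T)

    def mean(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def cov(self) -> np.ndarray:
        """Covariance of the KDE (data covariance + kernel covariance)."""
        base = np.cov(self.data.T) if self.n > 1 else np.zeros((self.d, self.d))
        return np.atleast_2d(base) + self.bandwidth

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points: data point + kernel noise, rejecting out-of-support."""
        out = np.empty((n, self.d))
        filled = 0
        chol = np.linalg.cholesky(self.bandwidth + 1e-300 * np.eye(self.d))
        while filled < n:
            m = max(n - filled, 16)
            idx = rng.integers(0, self.n, size=m)
            draws = self.data[idx] + rng.standard_normal((m, self.d)) @ chol.T
            ok = np.ones(m, dtype=bool)
            for j, lo in enumerate(self.lower):
                if lo is not None:
                    ok &= draws[:, j] >= lo
            good = draws[ok][: n - filled]
            out[filled:filled + len(good)] = good
            filled += len(good)
        return out


@dataclass
class StateDistributions:
    """Fitted joint pdfs per state x scenario plus transition bookkeeping.

    ``turn_prob[scenario]`` is the empirical probability that a curved walk
    away from the wall terminates in a sharp turn rather than a stop;
    ``boundary_ccw_prob[scenario]`` the probability that a wall excursion
    runs counter-clockwise (positive arc).
    """

    kdes: dict = field(default_factory=dict)        # (scenario, state) -> StateKDE
    turn_prob: dict = field(default_factory=dict)   # scenario -> float
    boundary_ccw_prob: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)      # (scenario, state) -> int

    def get(self, state: str, scenario: str) -> StateKDE:
        if scenario not in SCENARIOS:
            raise KeyError(f"unknown scenario {scenario!r}")
        if state not in STATE_FEATURES:
            raise KeyError(f"unknown state {state!r}")
        try:
            return self.kdes[(scenario, state)]
        except KeyError:
            raise KeyError(f"no fitted distribution for {state!r} in {scenario!r}")

    # --- protocol used by the simulator -------------------------------
    def sample_walk(self, scenario: str, rng: np.random.Generator):
        speed, dur, curv = self.get("curved_walk", scenario).sample(1, rng)[0]
        return float(speed), float(dur), float(curv)

    def sample_turn(self, scenario: str, rng: np.random.Generator):
        dur, total = self.get("sharp_turn", scenario).sample(1, rng)[0]
        return float(dur), float(total)

    def sample_stop(self, scenario: str, rng: np.random.Generator):
        dur, total = self.get("stop", scenario).sample(1, rng)[0]
        return float(dur), float(total)

    def sample_boundary(self, scenario: str, rng: np.random.Generator):
        dur, arc = self.get("boundary", scenario).sample(1, rng)[0]
        arc = abs(arc)
        if rng.random() >= self.boundary_ccw_prob.get(scenario, 0.5):
            arc = -arc
        return float(dur), float(arc)

    def sample_turn_prob(self, scenario: str) -> float:
        return float(self.turn_prob.get(scenario, 0.5))


def fit_state_distributions(segments: pd.DataFrame,
                            min_segments: int = 20) -> StateDistributions:
    """Fit the per-state, per-scenario joint KDEs from a segment table.

    Raises if any state x scenario cell has fewer than ``min_segments``
    observations, naming the deficient cell.
    """
    dist = StateDistributions()
    for scenario in SCENARIOS:
        sub = segments[segments["scenario"] == scenario]
        for state, feats in STATE_FEATURES.items():
            cell = sub[sub["state"] == state]
            if len(cell) < min_segments:
                if (scenario, state) in OPTIONAL_CELLS:
                    continue
                raise ValueError(
                    f"too few segments for state={state!r} scenario={scenario!r}: "
                    f"{len(cell)} < {min_segments}")
            data = cell.loc[:, list(feats)].to_numpy(dtype=float)
            dist.kdes[(scenario, state)] = StateKDE(data, _SUPPORT_LO[state])
            dist.counts[(scenario, state)] = len(cell)
        n_turn = dist.counts[(scenario, "sharp_turn")]
        n_stop = dist.counts[(scenario, "stop")]
        dist.turn_prob[scenario] = n_turn / (n_turn + n_stop)
        arcs = sub.loc[sub["state"] == "boundary", "total_curv_deg"].to_numpy()
        dist.boundary_ccw_prob[scenario] = float(np.mean(arcs > 0)) if len(arcs) else 0.5
    return dist


def sample_state(dist: StateDistributions, state: str, scenario: str,
                 rng: np.random.Generator) -> tuple:
    """One reproducible draw of the given state's parameter tuple."""
    if state == "curved_walk":
        return dist.sample_walk(scenario, rng)
    if state == "sharp_turn":
        return dist.sample_turn(scenario, rng)
    if state == "stop":
        return dist.sample_stop(scenario, rng)
    if state == "boundary":
        return dist.sample_boundary(scenario, rng)
    raise KeyError(f"unknown state {state!r}")


def save_distributions(dist: StateDistributions, path: str | Path) -> None:
    """Serialize to a single .npz archive (data points + bandwidths per cell)."""
    payload: dict[str, np.ndarray] = {"__version__": np.array([ARCHIVE_VERSION])}
    for (scenario, state), kde in dist.kdes.items():
        payload[f"data::{scenario}::{state}"] = kde.data
        payload[f"bw::{scenario}::{state}"] = kde.bandwidth
    for scenario in SCENARIOS:
        payload[f"meta::{scenario}"] = np.array([
            dist.turn_prob.get(scenario, 0.5),
            dist.boundary_ccw_prob.get(scenario, 0.5),
        ])
    np.savez(path, **payload)


def load_distributions(path: str | Path) -> StateDistributions:
    with np.load(path, allow_pickle=False) as archive:
        if int(archive["__version__"][0]) != ARCHIVE_VERSION:
            raise ValueError("unsupported distribution archive version")
        dist = StateDistributions()
        for key in archive.files:
            if key.startswith("data::"):
                _, scenario, state = key.split("::")
                dist.kdes[(scenario, state)] = StateKDE(
                    archive[key], _SUPPORT_LO[state])
                dist.counts[(scenario, state)] = archive[key].shape[0]
            elif key.startswith("meta::"):
                scenario = key.split("::")[1]
                turn_p, ccw_p = archive[key]
                dist.turn_prob[scenario] = float(turn_p)
                dist.boundary_ccw_prob[scenario] = float(ccw_p)
    return dist
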