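"""Ground-truth-labelled synthetic cohorts for end-to-end validation.

Every analysis step in this package (segmentation, density fitting, bias
estimation, border choice) is validated against cohorts generated here,
because the assay's empirical trajectories are not deposited. The generator
drives the WTSB simulator with fully parametric state distributions whose
moments are chosen to resemble a walking fly at desk scale: lognormal walk
speeds around 8 mm/s, gamma durations near 1 s (walks/stops) and several
seconds at the wall, Gaussian curvatures, and programmable turn bias and
border-choice excess. Optional Gaussian positional noise (default 0.15 mm,
the scale of centroid tracking error) emulates video tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .border_analysis import BorderModel
from .simulator import SimConfig, SimResult, simulate_fly
from .trajectory_io import ArenaConfig, Trajectory

__all__ = ["GroundTruthSpec", "ParametricStateDistributions",
           "generate_cohort", "light_profile", "recovery_spec"]


@dataclass(frozen=True)
class StateParams:
    """Parametric state-distribution parameters for one scenario."""

    walk_speed_median: float = 8.0       # mm/s, lognormal median
    walk_speed_sigma: float = 0.4        # lognormal sigma (log-space)
    walk_dur_shape: float = 2.0          # gamma
    walk_dur_scale: float = 0.5          # s -> mean 1 s
    walk_curv_sd: float = 2.0            # deg/frame, zero-mean Gaussian
    #: sharp turns last ~0.3 s and reorient by ~100 deg, i.e. they sustain
    #: per-frame curvature well above the ~14 deg/frame level that separates
    #: turns from walks in tracked flies
    turn_dur_shape: float = 4.0
    turn_dur_scale: float = 0.075        # s -> mean 0.3 s
    turn_mag_mean: float = 100.0         # deg, |total curvature|
    turn_mag_sd: float = 30.0
    turn_mag_min: float = 40.0
    stop_dur_shape: float = 2.0
    stop_dur_scale: float = 0.5
    stop_reorient_sd: float = 20.0       # deg
    boundary_dur_shape: float = 2.0
    boundary_dur_scale: float = 3.5      # s -> mean 7 s at the wall
    boundary_arc_lo: float = 20.0        # deg, |arc| uniform range
    boundary_arc_hi: float = 180.0
    turn_prob: float = 0.7               # walk -> turn (vs stop)


#: scenario-dependent defaults: inside the light-zone flies slow down and
#: walk for shorter bouts; their sharp turns grow larger near the border
DEFAULT_SCENARIO_PARAMS = {
    "before": StateParams(),
    "during_in": StateParams(walk_speed_median=4.0, walk_dur_scale=0.35),
    "during_out": StateParams(walk_speed_median=5.0, walk_dur_scale=0.4),
}


@dataclass(frozen=True)
class GroundTruthSpec:
    """Fully-known generating process for a synthetic cohort."""

    scenario_params: dict = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_PARAMS))
    turn_bias: float = 0.5
    border_excess_weight: float = 0.0    # point-mass weight at the border bin
    baseline: float = 0.2
    #: P(at least n turns | crossing track), n = 1, 2. Exit-to-entry tracks
    #: are long and nearly always contain turns; entry-to-exit tracks often
    #: traverse the light-zone without turning.
    p_atleast_out: tuple[float, float] = (0.9, 0.6)
    p_atleast_in: tuple[float, float] = (0.3, 0.15)
    noise_sd_mm: float = 0.15
    turn_style: str = "smooth"           # 'smooth' | 'split'
    turn_curv_jitter: float = 8.0        # deg/frame jitter within smooth turns
    turn_curv_profile: str = "bell"      # 'bell' | 'flat' curvature envelope
    turn_curv_mod: float = 0.5           # within-turn oscillation depth
    stop_creep_mm_s: float = 0.2         # residual speed during stops
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.turn_bias <= 1.0:
            raise ValueError("turn_bias must lie in [0, 1]")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if self.turn_style not in ("smooth", "split"):
            raise ValueError("turn_style must be 'smooth' or 'split'")


class ParametricStateDistributions:
    """State-sampling protocol backed by closed-form distributions."""

    def __init__(self, spec: GroundTruthSpec) -> None:
        self.spec = spec

    def _params(self, scenario: str) -> StateParams:
        return self.spec.scenario_params[scenario]

    def sample_walk(self, scenario, rng):
        p = self._params(scenario)
        speed = float(np.exp(np.log(p.walk_speed_median)
                             + p.walk_speed_sigma * rng.standard_normal()))
        dur = float(rng.gamma(p.walk_dur_shape, p.walk_dur_scale)) + 1e-3
        curv = float(rng.normal(0.0, p.walk_curv_sd))
        return speed, dur, curv

    def sample_turn(self, scenario, rng):
        p = self._params(scenario)
        dur = float(rng.gamma(p.turn_dur_shape, p.turn_dur_scale)) + 1e-3
        mag = abs(float(rng.normal(p.turn_mag_mean, p.turn_mag_sd)))
        mag = max(mag, p.turn_mag_min)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return dur, sign * mag

    def sample_stop(self, scenario, rng):
        p = self._params(scenario)
        dur = float(rng.gamma(p.stop_dur_shape, p.stop_dur_scale)) + 1e-3
        return dur, float(rng.normal(0.0, p.stop_reorient_sd))

    def sample_boundary(self, scenario, rng):
        p = self._params(scenario)
        dur = float(rng.gamma(p.boundary_dur_shape, p.boundary_dur_scale)) + 1e-3
        arc = float(rng.uniform(p.boundary_arc_lo, p.boundary_arc_hi))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return dur, sign * arc

    def sample_turn_prob(self, scenario) -> float:
        return self._params(scenario).turn_prob


def _border_model(spec: GroundTruthSpec, n_bins: int = 50) -> BorderModel:
    """Border model with a programmed point-mass excess at the border.

    The excess sits on each track kind's own side of the border (just
    outside it for exit-to-entry tracks, just inside for entry-to-exit
    tracks), where a crossing fly can actually reach it.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    inside_bin = int(np.clip(np.searchsorted(edges, 0.3, "left") - 1, 0, n_bins - 1))
    outside_bin = min(inside_bin + 1, n_bins - 1)
    base = np.full(n_bins, (1.0 - spec.border_excess_weight) / n_bins)

    def with_excess(j):
        f = base.copy()
        f[j] += spec.border_excess_weight
        return f / f.sum()

    return BorderModel(b=0.3, lam=5.0, baseline=spec.baseline,
                       turn_bias=spec.turn_bias, bin_edges=edges,
                       f_outside=with_excess(outside_bin),
                       f_inside=with_excess(inside_bin),
                       p_atleast_out=spec.p_atleast_out,
                       p_atleast_in=spec.p_atleast_in)


def generate_cohort(spec: GroundTruthSpec, arena: ArenaConfig | None = None,
                    n: int = 10, duration_s: float | None = None,
                    build_segments: bool = False) -> list[SimResult]:
    """Generate ``n`` ground-truth-labelled flies.

    Turn bias / border excess are active whenever programmed (the WTSB+BC+TB
    machinery with a synthetic border model); positional noise, if any, is
    added after generation and before any smoothing the caller applies.
    """
    arena = arena or ArenaConfig()
    dists = ParametricStateDistributions(spec)
    use_bc = spec.border_excess_weight > 0 or spec.turn_bias != 0.5
    cfg = SimConfig(
        dists=dists, arena=arena,
        model="WTSB_BC_TB" if use_bc else "WTSB",
        border_model=_border_model(spec) if use_bc else None,
        n_flies=n, seed=spec.seed, duration_s=duration_s,
        turn_style=spec.turn_style, turn_curv_jitter=spec.turn_curv_jitter,
        turn_curv_profile=spec.turn_curv_profile,
        turn_curv_mod=spec.turn_curv_mod,
        stop_creep_mm_s=spec.stop_creep_mm_s)
    out = []
    for i in range(n):
        rng = np.random.default_rng([spec.seed, i])
        res = simulate_fly(cfg, fly_id=i, rng=rng)
        if spec.noise_sd_mm > 0:
            x = res.traj.x + rng.normal(0, spec.noise_sd_mm, len(res.traj))
            y = res.traj.y + rng.normal(0, spec.noise_sd_mm, len(res.traj))
            # the wall is physical: fold noise-displaced points back inside
            r = np.hypot(x, y)
            Rmax = arena.arena_radius_mm
            scale = np.where(r > Rmax, Rmax / np.maximum(r, 1e-12), 1.0)
            res.traj.x, res.traj.y = x * scale, y * scale
        if build_segments:
            _ = res.segments
        out.append(res)
    return out


def recovery_spec(seed: int = 0) -> GroundTruthSpec:
    """Noise-free spec with well-separated curvature regimes.

    Walks stay below ~3 deg/frame of curvature while turns sustain around
    30 deg/frame, so every frame has an unambiguous state; used to measure
    frame-label recovery of the segmentation.
    """
    params = {
        scen: replace(p, walk_curv_sd=1.0, turn_mag_mean=430.0,
                      turn_mag_sd=30.0, turn_mag_min=360.0,
                      turn_dur_shape=16.0, turn_dur_scale=0.4 / 16.0)
        for scen, p in DEFAULT_SCENARIO_PARAMS.items()
    }
    return GroundTruthSpec(scenario_params=params, noise_sd_mm=0.0,
                           turn_style="smooth", turn_curv_jitter=1.5,
                           turn_curv_profile="flat", turn_curv_mod=0.45,
                           seed=seed)


def bias_probe_spec(turn_bias: float, seed: int = 0) -> GroundTruthSpec:
    """Cohort for validating the turn-direction choice in isolation.

    The inward/outward class of an executed turn is decided by its direction
    only when the turn magnitude Delta is small relative to the angle gamma
    between the approach and the inward radial vector; when Delta > 2*gamma
    (or the mirror case near gamma = 180 deg) both candidate directions land
    in the same class and no direction rule can realise the programmed
    probability on that turn. The measured inward fraction is therefore
    depressed by about bias * P(gamma < Delta/2) regardless of the rule, so
    the probe uses small turns (|total| ~ 6 deg) and strongly curved walks
    (heading decorrelates from the crossing geometry before the first turn),
    which keeps forced-class turns to a couple of percent.
    """
    params = {
        scen: replace(p, walk_curv_sd=4.0, turn_mag_mean=6.0,
                      turn_mag_sd=1.5, turn_mag_min=3.0)
        for scen, p in DEFAULT_SCENARIO_PARAMS.items()
    }
    return GroundTruthSpec(scenario_params=params, turn_bias=turn_bias,
                           border_excess_weight=0.0,
                           p_atleast_out=(0.0, 0.0), p_atleast_in=(0.0, 0.0),
                           noise_sd_mm=0.0, turn_style="split", seed=seed)


def light_profile(r_mm, arena: ArenaConfig | None = None):
    """Relative light intensity at radius r: 1 inside the full-intensity
    core, a linear ramp across the border, 0 beyond."""
    arena = arena or ArenaConfig()
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    ramp = (arena.light_zero_mm - r) / (arena.light_zero_mm - arena.light_full_mm)
    out = np.clip(ramp, 0.0, 1.0)
    out = np.where(r <= arena.light_full_mm, 1.0, out)
    return out if out.ndim else float(out)
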