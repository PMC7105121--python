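"""Generative walk-turn-stop-boundary (WTSB) model of arena locomotion.

A synthetic fly starts at the arena center heading along +x and alternates
curved walks with sharp turns, stops and wall (boundary) excursions, each
parameterized by draws from the fitted per-state joint pdfs of the current
scenario (before first light-zone entry / during-inside / during-outside).
Walks integrate constant sampled speed and per-frame curvature; sharp turns
run straight for half their duration, reorient instantaneously, and run
straight for the second half; stops hold position then reorient; boundary
excursions advance along the wall by a sampled arc then exit toward the
center +/- 10 degrees. The WTSB+BC+TB variant adds border choice (the first
two turns after a light-border crossing preferentially occur at radii drawn
from the fitted excess density) and turn bias (those turns are directed
inward with a set probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .border_analysis import BorderModel
from .kinematics import compute_kinematics
from .segmentation import first_entry_time, segment_track
from .trajectory_io import ArenaConfig, Trajectory

__all__ = ["SimConfig", "SimResult", "simulate_fly", "simulate_cohort",
           "select_flies"]


@dataclass
class SimConfig:
    """Configuration of one simulation run."""

    dists: object                          # StateDistributions-like protocol
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    model: str = "WTSB"                    # or "WTSB_BC_TB"
    border_model: BorderModel | None = None
    n_flies: int = 1
    seed: int = 0
    duration_s: float | None = None        # defaults to arena.total_s
    #: sharp-turn execution: 'split' = straight half, instantaneous
    #: reorientation, straight half; 'smooth' = sustained per-frame
    #: curvature with jitter (used by ground-truth generators)
    turn_style: str = "split"
    turn_curv_jitter: float = 0.0          # deg/frame, smooth style only
    turn_curv_mod: float = 0.5             # oscillation depth, smooth style
    turn_curv_profile: str = "bell"        # 'bell' | 'flat', smooth style
    #: residual speed while stopped (mm/s). 0 = hold position exactly and
    #: reorient at stop end; > 0 (below the stop threshold) = creep along
    #: the gradually rotating heading, which makes the reorientation visible
    #: to path-curvature measures as it is in tracked flies
    stop_creep_mm_s: float = 0.0
    #: selection criteria for synthetic cohorts
    outer_factor: float = 1.1
    inner_factor: float = 0.9
    first_entry_percentile: float = 85.0

    def __post_init__(self) -> None:
        if self.model not in ("WTSB", "WTSB_BC_TB"):
            raise ValueError("model must be 'WTSB' or 'WTSB_BC_TB'")
        if self.model == "WTSB_BC_TB" and self.border_model is None:
            raise ValueError("WTSB_BC_TB requires a border_model")
        if self.turn_style not in ("split", "smooth"):
            raise ValueError("turn_style must be 'split' or 'smooth'")
        if self.outer_factor <= 0 or self.inner_factor <= 0:
            raise ValueError("selection factors must be positive")


@dataclass
class SimResult:
    """One synthetic fly with full ground-truth state provenance."""

    traj: Trajectory
    labels: np.ndarray                     # per-frame true state label
    fly_id: int
    first_entry_time_s: float = float("nan")
    selected: bool = True
    turn_log: list = field(default_factory=list)
    _segments: pd.DataFrame | None = None
    _config: ArenaConfig | None = None

    @property
    def segments(self) -> pd.DataFrame:
        """Ground-truth segment table (built lazily from the provenance)."""
        if self._segments is None:
            kin = compute_kinematics(self.traj, self._config or ArenaConfig())
            self._segments = segment_track(self.traj, kin, labels=self.labels,
                                           config=self._config or ArenaConfig())
        return self._segments


class _FlyState:
    """Mutable bookkeeping while one fly is being generated."""

    __slots__ = ("x", "y", "heading", "frame", "first_entry", "inside",
                 "turns_since_cross", "track_kind", "walk_speed")

    def __init__(self) -> None:
        self.x = 0.0
        self.y = 0.0
        self.heading = 0.0
        self.frame = 0
        self.first_entry: int | None = None
        self.inside = True
        self.turns_since_cross = 0
        self.track_kind = "inside"
        self.walk_speed = 1.0


def _scenario(st: _FlyState, arena: ArenaConfig) -> str:
    if st.first_entry is None:
        return "before"
    r = float(np.hypot(st.x, st.y))
    return "during_in" if r < arena.border_radius_mm else "during_out"


def simulate_fly(cfg: SimConfig, fly_id: int = 0,
                 rng: np.random.Generator | None = None,
                 build_segments: bool = False) -> SimResult:
    """Generate one synthetic fly (bit-reproducible for a fixed seed/id)."""
    arena = cfg.arena
    if rng is None:
        rng = np.random.default_rng([cfg.seed, fly_id])
    fps = arena.fps
    dt = 1.0 / fps
    total = cfg.duration_s if cfg.duration_s is not None else arena.total_s
    n_frames = int(round(total * fps))
    R = arena.arena_radius_mm
    wall = R - arena.boundary_margin_mm
    b_mm = arena.border_radius_mm

    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    ths = np.empty(n_frames)
    labels = np.empty(n_frames, dtype=object)
    st = _FlyState()
    turn_log: list[dict] = []
    bc_active = cfg.model == "WTSB_BC_TB"

    def append(x_arr, y_arr, th_arr, label) -> int:
        """Write a chunk of frames, truncating at the 6-minute horizon."""
        m = min(len(x_arr), n_frames - st.frame)
        sl = slice(st.frame, st.frame + m)
        xs[sl], ys[sl], ths[sl] = x_arr[:m], y_arr[:m], th_arr[:m]
        labels[sl] = label
        st.frame += m
        if m:
            st.x, st.y, st.heading = float(x_arr[m - 1]), float(y_arr[m - 1]), float(th_arr[m - 1])
        # first-entry / crossing bookkeeping on the appended frames; only the
        # state after the last crossing matters for the next decision
        if m == 0:
            return m
        inside_chunk = np.hypot(x_arr[:m], y_arr[:m]) < b_mm
        start = st.frame - m
        j0 = 0
        if st.first_entry is None:
            t_chunk = (start + np.arange(m)) * dt
            entries = np.flatnonzero((t_chunk >= arena.light_on_s) & inside_chunk)
            if len(entries) == 0:
                return m
            st.first_entry = start + int(entries[0])
            st.inside = True
            st.turns_since_cross = 0
            st.track_kind = "inside"
            j0 = int(entries[0])
        prev = np.concatenate(([st.inside], inside_chunk[j0:]))
        if np.any(np.diff(prev.view(np.int8)) != 0):
            st.turns_since_cross = 0
        st.inside = bool(inside_chunk[-1])
        st.track_kind = "inside" if st.inside else "outside"
        return m

    def do_walk() -> str:
        """Integrate one curved walk; returns the terminating state."""
        scen = _scenario(st, arena)
        speed, dur, curv = cfg.dists.sample_walk(scen, rng)
        st.walk_speed = max(speed, 1e-3)
        m = max(1, int(round(dur * fps)))
        heads = st.heading + curv * np.arange(1, m + 1)
        step = st.walk_speed * dt
        x = st.x + np.cumsum(step * np.cos(np.radians(heads)))
        y = st.y + np.cumsum(step * np.sin(np.radians(heads)))
        r = np.hypot(x, y)

        # border choice: the first two turns after a light-border crossing
        # may be forced to occur at a radius drawn from the rectified excess
        # density. The governing crossing can either predate this walk
        # (turn counter still < 2) or happen inside it.
        hit = np.flatnonzero(r >= wall)
        end = hit[0] if len(hit) else m - 1
        nxt = None
        if bc_active:
            r0 = float(np.hypot(st.x, st.y))
            start_idx = None
            kind = None
            n_idx = 1
            if st.first_entry is not None and st.turns_since_cross < 2:
                start_idx, kind, n_idx = 0, st.track_kind, st.turns_since_cross + 1
            else:
                inside0 = r0 < b_mm
                flips = np.flatnonzero((r[:end + 1] < b_mm) != inside0)
                if len(flips):
                    c = int(flips[0])
                    flip_inside = bool(r[c] < b_mm)
                    time_ok = (st.frame + c) / fps >= arena.light_on_s
                    # before first entry only an entering flip after
                    # light-on engages border choice
                    if st.first_entry is not None or (flip_inside and time_ok):
                        start_idx = c
                        kind = "inside" if flip_inside else "outside"
            if start_idx is not None:
                bm = cfg.border_model
                p_force = (1.0 - bm.baseline) * bm.p_atleast(kind, n_idx)
                if rng.random() < p_force:
                    target = bm.sample_turn_radius(kind, rng) * R
                    ref = r0 if start_idx == 0 else r[start_idx]
                    seg_r = r[start_idx:end + 1]
                    crossed = np.flatnonzero(np.sign(seg_r - target)
                                             != np.sign(ref - target))
                    if len(crossed):
                        end = start_idx + int(crossed[0])
                        nxt = "sharp_turn"
        if nxt is None:
            if len(hit) and hit[0] <= end:
                end, nxt = hit[0], "boundary"
            else:
                scen_end = _scenario(st, arena)
                nxt = ("sharp_turn"
                       if rng.random() < cfg.dists.sample_turn_prob(scen_end)
                       else "stop")
        # keep the terminal frame physically inside the arena
        if r[end] > R - 0.01:
            scale = (R - 0.01) / r[end]
            x[end] *= scale
            y[end] *= scale
        append(x[:end + 1], y[:end + 1], heads[:end + 1], "curved_walk")
        return nxt

    def choose_turn_sign(total_mag: float, p1, p2) -> tuple[float, dict]:
        """Direction of a sharp turn; inward with probability = turn bias."""
        u = -np.asarray(p2)
        v1 = np.asarray(p2) - np.asarray(p1)
        biased = (bc_active and st.first_entry is not None
                  and st.turns_since_cross < 2)
        bias = cfg.border_model.turn_bias if biased else None

        def ang(v, w):
            nv, nw = np.hypot(*v), np.hypot(*w)
            if nv == 0 or nw == 0:
                return np.nan
            return np.degrees(np.arccos(np.clip(np.dot(v, w) / (nv * nw), -1, 1)))

        theta_before = ang(v1, u)
        cand = {}
        for sgn in (+1.0, -1.0):
            h = np.radians(st.heading + sgn * total_mag)
            v2 = np.array([np.cos(h), np.sin(h)])
            cand[sgn] = ang(v2, u)
        info = {"theta_before": theta_before, "biased": biased}
        if bias is None:
            # base model: direction is a fair coin on the sampled magnitude
            sgn = 1.0 if rng.random() < 0.5 else -1.0
            return sgn, info
        inward = {s: (not np.isnan(cand[s]) and not np.isnan(theta_before)
                      and cand[s] < theta_before - 1e-9) for s in cand}
        if inward[+1.0] != inward[-1.0]:
            in_sgn = +1.0 if inward[+1.0] else -1.0
            sgn = in_sgn if rng.random() < bias else -in_sgn
        else:
            sgn = 1.0 if rng.random() < 0.5 else -1.0  # geometry forces the class
        return sgn, info

    def _clamp(x, y, i):
        r = float(np.hypot(x[i], y[i]))
        if r > R - 0.01:
            x[i] *= (R - 0.01) / r
            y[i] *= (R - 0.01) / r

    def do_turn() -> str:
        scen = _scenario(st, arena)
        dur, total = cfg.dists.sample_turn(scen, rng)
        m = max(2, int(round(dur * fps)))
        p1 = (st.x, st.y)
        step = st.walk_speed * dt

        def straight(k):
            h = np.radians(st.heading)
            x = st.x + step * np.cos(h) * np.arange(1, k + 1)
            y = st.y + step * np.sin(h) * np.arange(1, k + 1)
            return x, y, np.full(k, st.heading)

        if cfg.turn_style == "smooth":
            # sustained curvature: direction decided at turn onset from the
            # inward vector at p1
            biased_here = (bc_active and st.first_entry is not None
                           and st.turns_since_cross < 2)
            if biased_here or cfg.model == "WTSB_BC_TB":
                sgn, info = choose_turn_sign(abs(total), p1, p1)
                signed_total = sgn * abs(total)
            else:
                signed_total = total
                info = {"biased": False}
            # curvature envelope carrying a few-frame oscillation: real sharp
            # turns sustain both high curvature and a high curvature
            # derivative throughout. 'bell' rises to ~2x the mean and falls;
            # 'flat' holds the mean level across the turn.
            t_idx = np.arange(m)
            if cfg.turn_curv_profile == "bell":
                prof = 1.0 - np.cos(2.0 * np.pi * (t_idx + 0.5) / m)
                if cfg.turn_curv_mod > 0 and m > 2:
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    prof = prof * (1.0 + cfg.turn_curv_mod
                                   * np.sin(2.0 * np.pi * t_idx / 5.0 + phase))
            else:
                # sustained level with a slow ripple; the half-period is kept
                # longer than the curvature-derivative stencil so |dk| dips
                # near ripple extrema stay isolated single frames
                prof = np.ones(m)
                if cfg.turn_curv_mod > 0 and m > 2:
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    prof = prof * (1.0 + cfg.turn_curv_mod
                                   * np.sin(2.0 * np.pi * t_idx / 8.0 + phase))
            dh = signed_total * prof / prof.sum()
            if cfg.turn_curv_jitter > 0 and m > 1:
                jit = rng.normal(0.0, cfg.turn_curv_jitter, size=m)
                dh += jit - jit.mean()
            heads = st.heading + np.cumsum(dh)
            x = st.x + np.cumsum(step * np.cos(np.radians(heads)))
            y = st.y + np.cumsum(step * np.sin(np.radians(heads)))
            r = np.hypot(x, y)
            hit = np.flatnonzero(r >= wall)
            end = hit[0] if len(hit) else m - 1
            _clamp(x, y, end)
            mid = min(end // 2, end)
            p2 = (float(x[mid]), float(y[mid]))
            # split the append at the curvature peak: a turn belongs to the
            # crossing track containing its peak, so crossings after the
            # peak must not transfer its count to the next track
            append(x[:mid + 1], y[:mid + 1], heads[:mid + 1], "sharp_turn")
            n_pre = st.turns_since_cross
            idx = n_pre + 1
            append(x[mid + 1:end + 1], y[mid + 1:end + 1],
                   heads[mid + 1:end + 1], "sharp_turn")
            if st.turns_since_cross == n_pre:
                st.turns_since_cross += 1
            turn_log.append({
                "frame": st.frame, "p1": p1, "p2": p2, "p3": (st.x, st.y),
                "signed_total": signed_total,
                "index_since_cross": idx,
                "track_kind": st.track_kind,
                "after_entry": st.first_entry is not None, **info,
            })
            return "boundary" if len(hit) else "curved_walk"

        half1 = m // 2
        half2 = m - half1
        x1, y1, t1 = straight(half1)
        # containment: truncate into a boundary excursion if the wall is hit
        r1 = np.hypot(x1, y1)
        hit = np.flatnonzero(r1 >= wall)
        if len(hit):
            _clamp(x1, y1, hit[0])
            append(x1[:hit[0] + 1], y1[:hit[0] + 1], t1[:hit[0] + 1], "sharp_turn")
            # the truncated turn still occupies a turn index in its track
            st.turns_since_cross += 1
            return "boundary"
        append(x1, y1, t1, "sharp_turn")
        p2 = (st.x, st.y)

        biased_here = (bc_active and st.first_entry is not None
                       and st.turns_since_cross < 2)
        if biased_here or cfg.model == "WTSB_BC_TB":
            sgn, info = choose_turn_sign(abs(total), p1, p2)
            signed_total = sgn * abs(total)
        else:
            signed_total = total
            info = {"biased": False}
        st.heading += signed_total
        n_pre = st.turns_since_cross
        idx = n_pre + 1
        x2, y2, t2 = straight(half2)
        r2 = np.hypot(x2, y2)
        hit = np.flatnonzero(r2 >= wall)
        end = hit[0] if len(hit) else half2 - 1
        _clamp(x2, y2, end)
        append(x2[:end + 1], y2[:end + 1], t2[:end + 1], "sharp_turn")
        # count the turn in the track holding its peak: a crossing during
        # the second half resets the counter for the next track instead
        if st.turns_since_cross == n_pre:
            st.turns_since_cross += 1
        turn_log.append({
            "frame": st.frame, "p1": p1, "p2": p2, "p3": (st.x, st.y),
            "signed_total": signed_total,
            "index_since_cross": idx,
            "track_kind": st.track_kind, "after_entry": st.first_entry is not None,
            **info,
        })
        return "boundary" if len(hit) else "curved_walk"

    def do_stop() -> str:
        scen = _scenario(st, arena)
        dur, total = cfg.dists.sample_stop(scen, rng)
        m = max(1, int(round(dur * fps)))
        if cfg.stop_creep_mm_s > 0:
            heads = st.heading + total * np.arange(1, m + 1) / m
            step = cfg.stop_creep_mm_s * dt
            x = st.x + np.cumsum(step * np.cos(np.radians(heads)))
            y = st.y + np.cumsum(step * np.sin(np.radians(heads)))
            append(x, y, heads, "stop")
        else:
            x = np.full(m, st.x)
            y = np.full(m, st.y)
            th = np.full(m, st.heading)
            append(x, y, th, "stop")
            st.heading += total        # reorientation applied at stop end
        return "curved_walk"

    def do_boundary() -> str:
        scen = _scenario(st, arena)
        dur, arc = cfg.dists.sample_boundary(scen, rng)
        m = max(1, int(round(dur * fps)))
        r0 = min(max(np.hypot(st.x, st.y), wall), R - 0.01)
        phi0 = np.degrees(np.arctan2(st.y, st.x))
        phis = phi0 + arc * np.arange(1, m + 1) / m
        x = r0 * np.cos(np.radians(phis))
        y = r0 * np.sin(np.radians(phis))
        # body tangent to the wall while circling
        th = phis + (90.0 if arc >= 0 else -90.0)
        append(x, y, th, "boundary")
        # leave toward the center +/- 10 degrees
        inward = np.degrees(np.arctan2(-st.y, -st.x))
        st.heading = inward + rng.uniform(-10.0, 10.0)
        return "curved_walk"

    dispatch = {"curved_walk": do_walk, "sharp_turn": do_turn,
                "stop": do_stop, "boundary": do_boundary}
    state = "curved_walk"
    while st.frame < n_frames:
        state = dispatch[state]()

    t = np.arange(n_frames) / fps
    traj = Trajectory(t=t, x=xs, y=ys, theta=np.mod(ths, 360.0))
    res = SimResult(traj=traj, labels=labels, fly_id=fly_id,
                    first_entry_time_s=first_entry_time(traj, arena),
                    turn_log=turn_log, _config=arena)
    if build_segments:
        _ = res.segments
    return res


def simulate_cohort(cfg: SimConfig, build_segments: bool = False) -> list[SimResult]:
    """Simulate ``cfg.n_flies`` independent flies (seed + fly index RNG)."""
    return [simulate_fly(cfg, fly_id=i, build_segments=build_segments)
            for i in range(cfg.n_flies)]


def select_flies(results: list[SimResult], cfg: SimConfig,
                 empirical_first_entries: list[float] | None = None,
                 use_percentile_rule: bool = True) -> list[SimResult]:
    """Apply the synthetic-fly inclusion criteria.

    A fly is kept if, in both the before and during periods, it reaches at
    least ``outer_factor`` x the light radius and comes within
    ``inner_factor`` x the light radius, and (optionally) if its first-entry
    time does not exceed the given percentile of the supplied reference
    first-entry times.
    """
    if use_percentile_rule:
        if not empirical_first_entries:
            raise ValueError("percentile rule needs reference first-entry times")
        cutoff = float(np.percentile(np.asarray(empirical_first_entries, float),
                                     cfg.first_entry_percentile))
    kept = []
    for res in results:
        arena = cfg.arena
        r = res.traj.r
        before = res.traj.t < arena.light_on_s
        during = ~before
        ok = True
        for mask in (before, during):
            if not mask.any():
                ok = False
                break
            ok &= bool(r[mask].max() >= cfg.outer_factor * arena.border_radius_mm)
            ok &= bool(r[mask].min() <= cfg.inner_factor * arena.border_radius_mm)
        if ok and use_percentile_rule:
            fe = res.first_entry_time_s
            ok = bool(np.isfinite(fe) and fe <= cutoff)
        res.selected = bool(ok)
        if ok:
            kept.append(res)
    return kept
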