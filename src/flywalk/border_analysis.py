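"""Turn bias, border choice and the turn-location detrend model.

A fly crossing the light border makes its first sharp turns unusually close
to the border, and those turns are biased inward. This module estimates
both effects from segment tables and builds the detrend function T(r) —
the turn-location density expected for border-crossing walks under uniform
start positions and exponentially distributed radial displacements — whose
subtraction from the empirical first-two-turn pmfs isolates the genuine
border-choice excess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .trajectory_io import ArenaConfig, Trajectory

__all__ = ["TurnGeometry", "BorderModel", "turn_geometries", "crossing_tracks",
           "estimate_turn_bias", "classify_optimal_turns", "turn_location_pmf",
           "fit_lambda", "detrend_T", "fit_border_choice",
           "first_turn_after_exit_stats", "bootstrap_ci"]


def bootstrap_ci(values: np.ndarray, statistic=np.mean, n_resamples: int = 10000,
                 confidence: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """BCa bootstrap CI (10,000 resamples by default)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2 or np.ptp(values) == 0:
        v = float(statistic(values)) if len(values) else float("nan")
        return (v, v)
    res = stats.bootstrap((values,), statistic, n_resamples=n_resamples,
                          confidence_level=confidence, method="BCa",
                          rng=np.random.default_rng(seed))
    return (float(res.confidence_interval.low), float(res.confidence_interval.high))


@dataclass
class TurnGeometry:
    """Geometry of one sharp turn: start, peak-curvature point and end."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    scenario: str = "before"
    turn_index: int | None = None   # 1-based index within its crossing track
    track_kind: str | None = None   # 'inside' | 'outside' | None

    @property
    def v1(self) -> np.ndarray:
        return self.p2 - self.p1

    @property
    def v2(self) -> np.ndarray:
        return self.p3 - self.p2

    @property
    def u(self) -> np.ndarray:
        """Inward radial vector from the turn location."""
        return -self.p2

    @staticmethod
    def _angle(v: np.ndarray, u: np.ndarray) -> float:
        nv, nu = np.linalg.norm(v), np.linalg.norm(u)
        if nv == 0 or nu == 0:
            return float("nan")
        c = np.clip(np.dot(v, u) / (nv * nu), -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    @property
    def theta_before(self) -> float:
        return self._angle(self.v1, self.u)

    @property
    def theta_after(self) -> float:
        return self._angle(self.v2, self.u)

    def inward(self, tol: float = 1e-9) -> bool | None:
        """True if inward, False if outward, None for ties/undefined."""
        tb, ta = self.theta_before, self.theta_after
        if np.isnan(tb) or np.isnan(ta) or abs(ta - tb) <= tol:
            return None
        return ta < tb


def turn_geometries(segments: pd.DataFrame, traj: Trajectory,
                    config: ArenaConfig | None = None) -> list[TurnGeometry]:
    """TurnGeometry for every sharp-turn segment, tagged with its position
    (turn index, inside/outside track) relative to light-border crossings."""
    config = config or ArenaConfig()
    turns = segments[segments["state"] == "sharp_turn"]
    tracks = crossing_tracks(traj, config, period="afe", require_closed=False)

    def locate(frame: int):
        for kind, s, e in tracks:
            if s <= frame <= e:
                return kind, (s, e)
        return None, None

    out: list[TurnGeometry] = []
    per_track_count: dict = {}
    for _, seg in turns.sort_values("start_frame").iterrows():
        f0, fp, f1 = int(seg.start_frame), int(seg.peak_frame), int(seg.end_frame)
        p = lambda f: np.array([traj.x[f], traj.y[f]])
        kind, span = locate(fp)
        idx = None
        if span is not None:
            per_track_count[span] = per_track_count.get(span, 0) + 1
            idx = per_track_count[span]
        out.append(TurnGeometry(p1=p(f0), p2=p(fp), p3=p(f1),
                                scenario=str(seg.scenario),
                                turn_index=idx, track_kind=kind))
    return out


def crossing_tracks(traj: Trajectory, config: ArenaConfig,
                    period: str = "afe",
                    require_closed: bool = True) -> list[tuple[str, int, int]]:
    """Split a trajectory into inside/outside tracks at light-border crossings.

    Inside tracks run entry -> exit, outside tracks exit -> entry.
    ``period`` selects frames before ('bfe') or after ('afe') the first
    light-zone entry following light-on; 'all' uses the whole track. With
    ``require_closed`` only tracks bounded by crossings on both sides are
    returned (the crossing tracks proper).
    """
    r = traj.r
    inside = r < config.border_radius_mm
    after_on = traj.t >= config.light_on_s
    entries = np.flatnonzero(after_on & inside)
    fe = entries[0] if len(entries) else len(r)
    if period == "afe":
        lo, hi = fe, len(r) - 1
    elif period == "bfe":
        lo, hi = 0, fe - 1
    elif period == "all":
        lo, hi = 0, len(r) - 1
    else:
        raise ValueError("period must be 'afe', 'bfe' or 'all'")
    if hi <= lo:
        return []
    flips = np.flatnonzero(np.diff(inside[lo:hi + 1].view(np.int8))) + lo
    bounds = [lo, *[f + 1 for f in flips], hi + 1]
    out = []
    for i in range(len(bounds) - 1):
        s, e = bounds[i], bounds[i + 1] - 1
        closed = i > 0 and i < len(bounds) - 2
        if require_closed and not closed:
            continue
        out.append(("inside" if inside[s] else "outside", s, e))
    return out


def estimate_turn_bias(segments: pd.DataFrame, traj: Trajectory,
                       config: ArenaConfig | None = None,
                       turns: list[TurnGeometry] | None = None,
                       seed: int = 0) -> dict:
    """Inward-turn fraction, overall and split by scenario and turn index.

    A turn is inward when theta_after < theta_before (angles of the pre- and
    post-turn movement vectors to the inward radial vector at the turn
    location); exact ties are excluded from both numerator and denominator.
    'first_two' covers turns with index <= 2 within their crossing track.
    """
    if turns is None:
        turns = turn_geometries(segments, traj, config)
    if not turns:
        raise ValueError("no sharp turns to estimate bias from")

    def frac(sel: list[TurnGeometry]):
        flags = [t.inward() for t in sel]
        flags = [f for f in flags if f is not None]
        if not flags:
            return {"bias": float("nan"), "n": 0, "ci": (float("nan"),) * 2}
        arr = np.array(flags, dtype=float)
        return {"bias": float(arr.mean()), "n": len(arr),
                "ci": bootstrap_ci(arr, seed=seed)}

    result = {"overall": frac(turns)}
    for scenario in ("before", "during_in", "during_out"):
        sel = [t for t in turns if t.scenario == scenario]
        if sel:
            result[scenario] = frac(sel)
    result["first_two"] = frac([t for t in turns
                                if t.turn_index is not None and t.turn_index <= 2])
    result["later"] = frac([t for t in turns
                            if t.turn_index is not None and t.turn_index > 2])
    return result


def classify_optimal_turns(turns: list[TurnGeometry], seed: int = 0) -> dict:
    """Fraction of turns executed toward the side of the inward radial vector.

    The optimal direction is the rotation sense (sign of the reorientation
    from v1 to v2) that matches the side on which the inward vector lies
    relative to the approach. Radially aligned approaches have no defined
    optimal side and are excluded.
    """
    flags = []
    for t in turns:
        side = float(t.v1[0] * t.u[1] - t.v1[1] * t.u[0])    # u's side of v1
        sense = float(t.v1[0] * t.v2[1] - t.v1[1] * t.v2[0])  # rotation sense
        if abs(side) < 1e-12 or abs(sense) < 1e-12:
            continue
        flags.append(float(np.sign(side) == np.sign(sense)))
    if not flags:
        raise ValueError("no classifiable turns (all radially aligned)")
    arr = np.array(flags)
    return {"fraction_optimal": float(arr.mean()), "n": len(arr),
            "ci": bootstrap_ci(arr, seed=seed)}


def turn_location_pmf(segments: pd.DataFrame, traj: Trajectory,
                      config: ArenaConfig, first_n: int = 2,
                      n_bins: int = 50,
                      turns: list[TurnGeometry] | None = None):
    """pmfs of the first ``first_n`` turn locations per crossing track.

    Locations are the normalized radius of the peak-curvature point;
    returns (P_out, P_in, bin_edges) over r in [0, 1].
    """
    if turns is None:
        turns = turn_geometries(segments, traj, config)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    sel = [t for t in turns if t.turn_index is not None and t.turn_index <= first_n]
    if not any(t.track_kind in ("inside", "outside") for t in sel):
        raise ValueError("no crossing tracks with turns")
    pmfs = {}
    for kind in ("outside", "inside"):
        rs = [np.linalg.norm(t.p2) / config.arena_radius_mm
              for t in sel if t.track_kind == kind]
        hist, _ = np.histogram(np.clip(rs, 0, 1 - 1e-12), bins=edges)
        total = hist.sum()
        pmfs[kind] = hist / total if total else np.zeros(n_bins)
    return pmfs["outside"], pmfs["inside"], edges


def fit_lambda(segments: pd.DataFrame, traj: Trajectory,
               config: ArenaConfig) -> float:
    """MLE exponential rate of normalized radial displacement per curved walk.

    Uses curved walks inside crossing tracks of the before-first-entry
    period; the rate is 1 / mean |Delta r| (r normalized to arena radius).
    """
    tracks = crossing_tracks(traj, config, period="bfe", require_closed=False)
    disp = []
    walks = segments[segments["state"] == "curved_walk"]
    rnorm = traj.r / config.arena_radius_mm
    for _, seg in walks.iterrows():
        s, e = int(seg.start_frame), int(seg.end_frame)
        if any(ts <= s and e <= te for _, ts, te in tracks):
            disp.append(abs(rnorm[e] - rnorm[s]))
    disp = np.asarray(disp)
    disp = disp[disp > 0]
    if len(disp) == 0:
        raise ValueError("no before-period curved walks with radial displacement")
    return float(1.0 / disp.mean())


def detrend_T(r, lam: float, b: float):
    """Turn-location density T(r) expected for border-crossing walks.

    Closed form of the convolution of a uniform start-location density with
    an exponential(lam) radial-displacement density, restricted to walks
    that cross the border b:

        T(r) = exp(lam*(r-b)) - exp(lam*(r-1))   for 0 <= r <= b
        T(r) = exp(-lam*(r-b)) - exp(-lam*r)     for b <  r <= 1
        T(r) = 0                                 otherwise

    The r <= b branch comes from inward crossings (starts uniform on (b,1)),
    the r > b branch from outward crossings (starts uniform on (0,b)). The
    two branches carry their own (unequal) normalizations, so T is generally
    discontinuous at r = b; downstream use normalizes over the grid.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not 0.0 < b < 1.0:
        raise ValueError("b must lie in (0, 1)")
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    lo = (r >= 0) & (r <= b)
    hi = (r > b) & (r <= 1)
    out[lo] = np.exp(lam * (r[lo] - b)) - np.exp(lam * (r[lo] - 1.0))
    out[hi] = np.exp(-lam * (r[hi] - b)) - np.exp(-lam * r[hi])
    return out if out.ndim else float(out)


def detrend_T_numeric(r, lam: float, b: float):
    """Quadrature evaluation of the defining convolution (oracle for detrend_T).

    Outward crossings: start L ~ U(0, b), displacement +x with density
    lam*exp(-lam*x); inward crossings: L ~ U(b, 1), displacement -x. Each
    branch is integrated numerically and rescaled by its uniform width so it
    is directly comparable with the unnormalized closed form.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    for i, ri in enumerate(r):
        if 0 <= ri <= b:
            val, _ = integrate.quad(
                lambda u: lam * np.exp(-lam * (u - ri)), max(ri, b), 1.0,
                epsabs=1e-12, epsrel=1e-12)
            out[i] = val
        elif b < ri <= 1:
            val, _ = integrate.quad(
                lambda u: lam * np.exp(-lam * (ri - u)), 0.0, min(ri, b),
                epsabs=1e-12, epsrel=1e-12)
            out[i] = val
    return out


@dataclass
class BorderModel:
    """Fitted border-choice model used by the WTSB+BC+TB simulator."""

    b: float = 0.3
    lam: float = 5.0
    baseline: float = 0.2
    turn_bias: float = 0.5
    bin_edges: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 51))
    f_outside: np.ndarray | None = None
    f_inside: np.ndarray | None = None
    #: P(at least n turns | track kind), n = 1, 2
    p_atleast_out: tuple[float, float] = (1.0, 1.0)
    p_atleast_in: tuple[float, float] = (1.0, 1.0)

    def f(self, kind: str) -> np.ndarray:
        return self.f_outside if kind == "outside" else self.f_inside

    def p_atleast(self, kind: str, n: int) -> float:
        p = self.p_atleast_out if kind == "outside" else self.p_atleast_in
        return p[min(n, 2) - 1]

    def sample_turn_radius(self, kind: str, rng: np.random.Generator) -> float:
        """Draw a normalized turn radius from the rectified excess density."""
        f = self.f(kind)
        if f is None:
            raise ValueError(f"no fitted density for {kind!r} tracks")
        j = rng.choice(len(f), p=f)
        lo, hi = self.bin_edges[j], self.bin_edges[j + 1]
        return float(lo + (hi - lo) * rng.random())


def fit_border_choice(P_out: np.ndarray, P_in: np.ndarray,
                      T_vals: np.ndarray, baseline: float = 0.2,
                      counts_out=None, counts_in=None,
                      bin_edges: np.ndarray | None = None,
                      b: float = 0.3, lam: float = 5.0,
                      turn_bias: float = 0.5) -> BorderModel:
    """Rectified, normalized border-choice densities plus turn-count attenuation.

    f = max(0, P - T_norm) / sum(...), with the detrend first normalized to a
    pmf on the same grid (the fit is therefore invariant to rescaling T by a
    positive constant). ``counts_out``/``counts_in`` are per-crossing-track
    turn counts from which P(at least n turns | track) is estimated.
    """
    T_vals = np.asarray(T_vals, dtype=float)
    if T_vals.sum() <= 0:
        raise ValueError("degenerate detrend (all zero)")
    T_norm = T_vals / T_vals.sum()

    def rectify(P):
        excess = np.maximum(0.0, np.asarray(P, dtype=float) - T_norm)
        total = excess.sum()
        if total <= 0:
            raise ValueError("rectified density is zero everywhere "
                             "(pmf indistinguishable from the detrend)")
        return excess / total

    def atleast(counts):
        if counts is None or len(counts) == 0:
            return (1.0, 1.0)
        c = np.asarray(counts)
        return (float(np.mean(c >= 1)), float(np.mean(c >= 2)))

    n_bins = len(T_norm)
    edges = bin_edges if bin_edges is not None else np.linspace(0, 1, n_bins + 1)
    return BorderModel(b=b, lam=lam, baseline=baseline, turn_bias=turn_bias,
                       bin_edges=np.asarray(edges),
                       f_outside=rectify(P_out), f_inside=rectify(P_in),
                       p_atleast_out=atleast(counts_out),
                       p_atleast_in=atleast(counts_in))


def first_turn_after_exit_stats(segments: pd.DataFrame, traj: Trajectory,
                                config: ArenaConfig, seed: int = 0) -> dict:
    """Time and radial distance of the first sharp turn after each light-zone
    exit (excursions with no turn before re-entry are excluded but counted)."""
    tracks = crossing_tracks(traj, config, period="afe", require_closed=False)
    exits = [(s, e) for kind, s, e in tracks if kind == "outside" and s > 0]
    if not exits:
        raise ValueError("no light-zone exits")
    turns = segments[segments["state"] == "sharp_turn"].sort_values("start_frame")
    times, dists = [], []
    excluded = 0
    for s, e in exits:
        in_win = turns[(turns["peak_frame"] >= s) & (turns["peak_frame"] <= e)]
        if len(in_win) == 0:
            excluded += 1
            continue
        fp = int(in_win.iloc[0]["peak_frame"])
        times.append(traj.t[fp] - traj.t[s])
        dists.append(traj.r[fp] - config.border_radius_mm)
    if not times:
        raise ValueError("no exits followed by a sharp turn")
    times, dists = np.asarray(times), np.asarray(dists)
    return {
        "time_s": times, "dist_mm": dists,
        "mean_time_s": float(times.mean()), "mean_dist_mm": float(dists.mean()),
        "ci_time_s": bootstrap_ci(times, seed=seed),
        "ci_dist_mm": bootstrap_ci(dists, seed=seed),
        "n_excursions_excluded": excluded,
    }
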