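import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flywalk.border_analysis import (TurnGeometry, classify_optimal_turns,
                                     crossing_tracks, detrend_T,
                                     detrend_T_numeric, estimate_turn_bias,
                                     fit_border_choice, fit_lambda,
                                     first_turn_after_exit_stats,
                                     turn_location_pmf)
from flywalk.trajectory_io import ArenaConfig, Trajectory


def _turn(p1, p2, p3):
    return TurnGeometry(np.asarray(p1, float), np.asarray(p2, float),
                        np.asarray(p3, float))


class TestTurnGeometry:
    def test_turn_ending_toward_origin_is_inward(self):
        t = _turn([10, 2], [12, 2], [11, 1.8])
        assert t.theta_after < t.theta_before
        assert t.inward() is True

    def test_reflected_exit_is_a_tie(self):
        # v2 = reflection of v1 about the radial direction at p2 -> equal
        # angles to the inward vector -> excluded
        p2 = np.array([10.0, 0.0])
        v1 = np.array([1.0, 0.5])
        v2 = np.array([1.0, -0.5])       # reflection about the x-axis (radial)
        t = _turn(p2 - v1, p2, p2 + v2)
        assert t.inward() is None

    def test_programmed_bernoulli_bias_recovered(self, rng):
        # constructed turns: inward with probability 0.7
        flags = []
        for _ in range(1000):
            ang = rng.uniform(0, 2 * np.pi)
            p2 = 10.0 * np.array([np.cos(ang), np.sin(ang)])
            u = -p2 / np.linalg.norm(p2)
            tang = np.array([-u[1], u[0]])
            inward = rng.random() < 0.7
            v1 = tang                                  # approach tangential
            v2 = (u if inward else -u) * 0.8 + tang * 0.2
            t = _turn(p2 - v1, p2, p2 + v2)
            flags.append(t.inward())
        est = np.mean([f for f in flags if f is not None])
        assert est == pytest.approx(0.7, abs=0.04)


class TestOptimalTurns:
    def test_turn_toward_radial_side_is_optimal(self):
        p2 = np.array([15.0, 0.0])
        v1 = np.array([0.0, 1.0])       # heading +y, center is to the left
        v2 = np.array([-0.5, 1.0])      # turning left, toward center
        out = classify_optimal_turns([_turn(p2 - v1, p2, p2 + v2)])
        assert out["fraction_optimal"] == 1.0

    def test_symmetric_directions_near_half(self, rng):
        turns = []
        for _ in range(500):
            ang = rng.uniform(0, 2 * np.pi)
            p2 = 15.0 * np.array([np.cos(ang), np.sin(ang)])
            v1 = np.array([np.cos(ang + np.pi / 2), np.sin(ang + np.pi / 2)])
            sgn = 1.0 if rng.random() < 0.5 else -1.0
            rot = np.radians(sgn * 40.0)
            c, s = np.cos(rot), np.sin(rot)
            v2 = np.array([c * v1[0] - s * v1[1], s * v1[0] + c * v1[1]])
            turns.append(_turn(p2 - v1, p2, p2 + v2))
        out = classify_optimal_turns(turns)
        assert out["fraction_optimal"] == pytest.approx(0.5, abs=0.07)

    def test_radially_aligned_turns_excluded(self):
        p2 = np.array([15.0, 0.0])
        v1 = np.array([-1.0, 0.0])       # heading straight at the center
        v2 = np.array([-1.0, 0.1])
        with pytest.raises(ValueError):
            classify_optimal_turns([_turn(p2 - v1, p2, p2 + v2)])


class TestDetrend:
    def test_vanishes_as_rate_goes_to_zero(self):
        r = np.linspace(0, 1, 50)
        T = detrend_T(r, 1e-9, 0.3)
        assert np.all(np.abs(T) < 1e-8)

    @pytest.mark.parametrize("lam,b", [(5.0, 0.3), (2.0, 0.5), (10.0, 0.3)])
    def test_closed_form_matches_convolution_quadrature(self, lam, b):
        r = np.linspace(0.0, 1.0, 100)
        closed = detrend_T(r, lam, b)
        numeric = detrend_T_numeric(r, lam, b)
        assert np.max(np.abs(closed - numeric)) < 1e-6

    def test_monte_carlo_crossing_model_matches(self):
        # uniform starts, exponential radial displacements, keep crossers
        rng = np.random.default_rng(0)
        lam, b, N = 5.0, 0.3, 10 ** 5
        u = rng.uniform(0, 1, N)
        d = rng.exponential(1 / lam, N)
        end = np.where(u < b, u + d, u - d)
        crossed = np.where(u < b, (end > b) & (end <= 1), (end < b) & (end >= 0))
        edges = np.linspace(0, 1, 51)
        hist, _ = np.histogram(end[crossed], bins=edges)
        p_mc = hist / hist.sum()
        T = detrend_T((edges[:-1] + edges[1:]) / 2, lam, b)
        p_T = T / T.sum()
        tv = 0.5 * np.sum(np.abs(p_mc - p_T))
        assert tv < 0.02

    @given(lam=st.floats(0.1, 20.0), b=st.floats(0.05, 0.95),
           r=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_on_support(self, lam, b, r):
        assert detrend_T(np.array([r]), lam, b)[0] >= -1e-12

    def test_zero_outside_unit_interval(self):
        T = detrend_T(np.array([-0.2, 1.3]), 5.0, 0.3)
        np.testing.assert_array_equal(T, 0.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            detrend_T(0.5, -1.0, 0.3)
        with pytest.raises(ValueError):
            detrend_T(0.5, 5.0, 1.5)


class TestBorderChoiceFit:
    def _uniform_T(self, n=50):
        return detrend_T(np.linspace(0.005, 0.995, n), 5.0, 0.3)

    def test_pmf_equal_to_detrend_is_degenerate(self):
        T = self._uniform_T()
        P = T / T.sum()
        with pytest.raises(ValueError):
            fit_border_choice(P, P, T)

    def test_border_spike_concentrates_density(self):
        T = self._uniform_T()
        P = T / T.sum() * 0.6
        P[15] += 0.4                       # excess at r ~ 0.31
        model = fit_border_choice(P, P, T, counts_out=[1, 2, 0, 1],
                                  counts_in=[1, 0, 0, 2])
        assert model.f_outside.argmax() == 15
        assert model.f_outside.sum() == pytest.approx(1.0)
        assert model.f_inside.sum() == pytest.approx(1.0)
        assert model.p_atleast_out == (0.75, 0.25)
        assert model.p_atleast_in == (0.5, 0.25)

    def test_invariant_to_rescaling_detrend(self):
        T = self._uniform_T()
        P = T / T.sum() * 0.7
        P[10] += 0.3
        m1 = fit_border_choice(P, P, T)
        m2 = fit_border_choice(P, P, 17.3 * T)
        np.testing.assert_allclose(m1.f_outside, m2.f_outside, atol=1e-12)

    def test_sampled_radii_follow_density(self, rng):
        T = self._uniform_T()
        P = T / T.sum() * 0.5
        P[15] += 0.5
        model = fit_border_choice(P, P, T)
        draws = [model.sample_turn_radius("outside", rng) for _ in range(2000)]
        frac_in_bin = np.mean((np.array(draws) >= 0.30) & (np.array(draws) < 0.32))
        assert frac_in_bin > 0.3


class TestTrackLevelEstimators:
    def _weaving_traj(self, arena, n_cross=6):
        """Fly oscillating radially across the light border after light-on."""
        fps = arena.fps
        t_on = int(arena.light_on_s * fps)
        n = t_on + 1800
        t = np.arange(n) / fps
        r = np.full(n, 20.0)
        # before light-on sit outside; afterwards weave 8 <-> 16 mm
        phase = np.linspace(0, n_cross * np.pi, n - t_on)
        r[t_on:] = 12.0 + 4.0 * np.cos(phase)
        x = r
        y = np.zeros(n)
        return Trajectory(t=t, x=x, y=y, theta=np.zeros(n))

    def test_crossing_tracks_alternate_kinds(self, arena):
        traj = self._weaving_traj(arena)
        tracks = crossing_tracks(traj, arena, period="afe")
        kinds = [k for k, _, _ in tracks]
        assert len(tracks) >= 3
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_turn_pmf_point_mass(self, arena):
        traj = self._weaving_traj(arena)
        tracks = crossing_tracks(traj, arena, period="afe", require_closed=False)
        rows = []
        for kind, s, e in tracks:
            mid = (s + e) // 2
            rows.append({"state": "sharp_turn", "start_frame": mid - 2,
                         "end_frame": mid + 2, "peak_frame": mid,
                         "scenario": "during_in" if kind == "inside" else "during_out"})
        seg = pd.DataFrame(rows)
        P_out, P_in, edges = turn_location_pmf(seg, traj, arena, first_n=2)
        assert P_out.sum() == pytest.approx(1.0)
        assert P_in.sum() == pytest.approx(1.0)
        # outside-track turns at the weave apex r = 16 mm -> 0.4 normalized
        center = (edges[P_out.argmax()] + edges[P_out.argmax() + 1]) / 2
        assert center == pytest.approx(0.4, abs=0.03)

    def test_estimate_turn_bias_requires_turns(self, arena):
        traj = self._weaving_traj(arena)
        seg = pd.DataFrame({"state": ["stop"], "start_frame": [0],
                            "end_frame": [10], "peak_frame": [5],
                            "scenario": ["before"]})
        with pytest.raises(ValueError):
            estimate_turn_bias(seg, traj, arena)

    def test_lambda_mle_on_known_displacements(self, arena):
        # deterministic weave: every qualifying walk moves |dr| = 1/6 of the
        # arena radius, so the exponential-rate MLE 1/mean(|dr|) equals 6
        fps = arena.fps
        dr = 40.0 / 6.0
        r_seq = [2.0]
        for _ in range(30):                 # up-leg: 2 -> 22 mm in 3 walks
            r_seq.append(r_seq[-1] + dr)
            if r_seq[-1] > 20.0:
                while r_seq[-1] > 2.5:      # down-leg back to 2 mm
                    r_seq.append(r_seq[-1] - dr)
        n_f = 10
        seg_rows, r_vals = [], []
        frame = 0
        for a, b in zip(r_seq[:-1], r_seq[1:]):
            seg_rows.append({"state": "curved_walk", "start_frame": frame,
                             "end_frame": frame + n_f - 1, "peak_frame": frame,
                             "scenario": "before"})
            r_vals.extend(np.linspace(a, b, n_f).tolist())
            frame += n_f
        r_arr = np.array(r_vals)
        traj = Trajectory(t=np.arange(frame) / fps, x=r_arr,
                          y=np.zeros(frame), theta=np.zeros(frame))
        lam_hat = fit_lambda(pd.DataFrame(seg_rows), traj, arena)
        assert lam_hat == pytest.approx(6.0, rel=1e-6)

    def test_first_turn_after_exit_fixed_delay(self, arena):
        traj = self._weaving_traj(arena)
        tracks = crossing_tracks(traj, arena, period="afe", require_closed=False)
        rows = []
        delay = 15    # frames = 0.5 s after each exit
        for kind, s, e in tracks:
            if kind == "outside" and s > 0 and s + delay <= e:
                rows.append({"state": "sharp_turn", "start_frame": s + delay - 1,
                             "end_frame": s + delay + 1, "peak_frame": s + delay,
                             "scenario": "during_out"})
        out = first_turn_after_exit_stats(pd.DataFrame(rows), traj, arena)
        assert out["mean_time_s"] == pytest.approx(delay / arena.fps, abs=0.05)
        assert np.std(out["time_s"]) < 1e-9

    def test_no_exits_rejected(self, arena):
        n = 12000
        traj = Trajectory(t=np.arange(n) / arena.fps, x=np.full(n, 5.0),
                          y=np.zeros(n), theta=np.zeros(n))
        seg = pd.DataFrame({"state": ["sharp_turn"], "start_frame": [100],
                            "end_frame": [110], "peak_frame": [105],
                            "scenario": ["before"]})
        with pytest.raises(ValueError):
            first_turn_after_exit_stats(seg, traj, arena)


class TestBiasOnCohort:
    def test_rotation_invariance_of_turn_bias(self, small_cohort, arena):
        res = small_cohort[3]
        seg = res.segments
        base = estimate_turn_bias(seg, res.traj, arena, seed=0)
        ang = np.radians(73.0)
        c, s = np.cos(ang), np.sin(ang)
        rot = Trajectory(t=res.traj.t, x=c * res.traj.x - s * res.traj.y,
                         y=s * res.traj.x + c * res.traj.y,
                         theta=res.traj.theta + 73.0)
        rotated = estimate_turn_bias(seg, rot, arena, seed=0)
        assert rotated["overall"]["bias"] == pytest.approx(
            base["overall"]["bias"], abs=1e-9)
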