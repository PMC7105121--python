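import numpy as np
import pytest

from flywalk.border_analysis import turn_geometries
from flywalk.simulator import SimConfig, SimResult, select_flies, simulate_cohort, simulate_fly
from flywalk.synthetic_data import (GroundTruthSpec, ParametricStateDistributions,
                                    _border_model, bias_probe_spec)
from flywalk.trajectory_io import ArenaConfig, Trajectory


class _DegenerateDists:
    """Zero-curvature, fixed-speed walks: the fly marches straight at the wall."""

    def sample_walk(self, scenario, rng):
        return 10.0, 5.0, 0.0

    def sample_turn(self, scenario, rng):
        return 0.3, 90.0

    def sample_stop(self, scenario, rng):
        return 0.5, 0.0

    def sample_boundary(self, scenario, rng):
        return 1.0, 45.0

    def sample_turn_prob(self, scenario):
        return 1.0


@pytest.fixture(scope="module")
def base_spec():
    return GroundTruthSpec(seed=100, noise_sd_mm=0.0, turn_style="split")


@pytest.fixture(scope="module")
def base_dists(base_spec):
    return ParametricStateDistributions(base_spec)


class TestStateMachine:
    def test_straight_walker_reaches_wall_then_boundary(self, arena):
        cfg = SimConfig(dists=_DegenerateDists(), seed=0, duration_s=20.0)
        res = simulate_fly(cfg)
        # straight to the wall: boundary engages within the 1.5 mm margin
        first_boundary = np.flatnonzero(res.labels == "boundary")[0]
        r_at = res.traj.r[first_boundary]
        assert r_at >= arena.arena_radius_mm - arena.boundary_margin_mm - 0.5
        # the walk before it is straight along +x
        assert np.allclose(res.traj.y[:first_boundary - 1], 0.0, atol=1e-9)

    def test_containment_many_flies(self, base_dists, arena):
        cfg = SimConfig(dists=base_dists, seed=5, n_flies=50, duration_s=60.0)
        for res in simulate_cohort(cfg):
            assert res.traj.r.max() <= arena.arena_radius_mm
            # boundary labels only within the wall margin
            bnd = res.labels == "boundary"
            if bnd.any():
                assert res.traj.r[bnd].min() >= arena.arena_radius_mm \
                    - arena.boundary_margin_mm - 1e-6

    def test_bit_reproducible_under_fixed_seed(self, base_dists):
        cfg = SimConfig(dists=base_dists, seed=77)
        a = simulate_fly(cfg, fly_id=3)
        b = simulate_fly(cfg, fly_id=3)
        assert np.array_equal(a.traj.x, b.traj.x)
        assert np.array_equal(a.traj.theta, b.traj.theta)
        assert (a.labels == b.labels).all()

    def test_provenance_tiles_trajectory(self, base_dists):
        cfg = SimConfig(dists=base_dists, seed=8)
        res = simulate_fly(cfg)
        assert len(res.labels) == len(res.traj)
        assert set(np.unique(res.labels)) <= {"boundary", "stop", "sharp_turn",
                                              "curved_walk"}

    def test_state_time_fractions_match_renewal_expectation(self, arena):
        # identical parameters in every scenario, speeds too low to reach the
        # wall: expected fractions follow the renewal weights
        # E[dur_state] * P(visit state per cycle)
        from dataclasses import replace

        from flywalk.synthetic_data import DEFAULT_SCENARIO_PARAMS

        params = {s: replace(DEFAULT_SCENARIO_PARAMS["before"],
                             walk_speed_median=1.0, walk_speed_sigma=0.2)
                  for s in DEFAULT_SCENARIO_PARAMS}
        spec = GroundTruthSpec(scenario_params=params, seed=31,
                               noise_sd_mm=0.0, turn_style="split")
        cfg = SimConfig(dists=ParametricStateDistributions(spec), seed=31,
                        turn_style="split")
        fracs = []
        for i in range(60):
            res = simulate_fly(cfg, fly_id=i)
            fracs.append([np.mean(res.labels == s)
                          for s in ("curved_walk", "sharp_turn", "stop")])
        fracs = np.array(fracs)
        # weights: walk E[dur]=1.0 s; turn p=0.7, E=0.3 s; stop p=0.3, E=1.0 s
        expected = np.array([1.0, 0.21, 0.30])
        expected = expected / expected.sum()
        renorm = fracs / fracs.sum(axis=1, keepdims=True)
        se = renorm.std(axis=0) / np.sqrt(len(fracs))
        # small bias from frame rounding of sampled durations: allow 3 SE
        # plus half a frame per state visit
        assert np.all(np.abs(renorm.mean(axis=0) - expected) < 3 * se + 0.02)


class TestBorderChoice:
    def test_point_mass_density_forces_border_turns(self, base_spec, base_dists):
        from dataclasses import replace
        spec = replace(base_spec, turn_bias=0.5, border_excess_weight=1.0,
                       baseline=0.0, p_atleast_out=(1.0, 1.0),
                       p_atleast_in=(1.0, 1.0))
        bm = _border_model(spec)
        cfg = SimConfig(dists=base_dists, model="WTSB_BC_TB", border_model=bm,
                        seed=12)
        arena = ArenaConfig()
        radii = []
        for i in range(15):
            res = simulate_fly(cfg, fly_id=i)
            for e in res.turn_log:
                if e.get("biased"):
                    radii.append(np.hypot(*e["p1"]) / arena.arena_radius_mm)
        radii = np.array(radii)
        assert len(radii) > 50
        # forced first turns initiate at the border bins (walks that end
        # before reaching the target fall back to the base process)
        assert np.mean(np.abs(radii - 0.3) < 0.05) > 0.6

    def test_later_turns_unaffected_by_border_density(self, base_spec, base_dists):
        from dataclasses import replace
        spec = replace(base_spec, turn_bias=0.5, border_excess_weight=1.0,
                       baseline=0.0)
        bm = _border_model(spec)
        cfg = SimConfig(dists=base_dists, model="WTSB_BC_TB", border_model=bm,
                        seed=13)
        arena = ArenaConfig()
        later = []
        for i in range(15):
            res = simulate_fly(cfg, fly_id=i)
            for e in res.turn_log:
                if e["after_entry"] and e["index_since_cross"] > 2:
                    later.append(np.hypot(*e["p1"]) / arena.arena_radius_mm)
        later = np.array(later)
        if len(later) > 30:
            assert np.mean(np.abs(later - 0.3) < 0.05) < 0.5


class TestTurnBias:
    def test_bias_one_always_turns_inward_when_possible(self):
        spec = bias_probe_spec(1.0, seed=7)
        cfg = SimConfig(dists=ParametricStateDistributions(spec),
                        model="WTSB_BC_TB", border_model=_border_model(spec),
                        seed=7, turn_style="split")
        arena = ArenaConfig()
        flags = []
        for i in range(40):
            res = simulate_fly(cfg, fly_id=i)
            for t in turn_geometries(res.segments, res.traj, arena):
                if t.turn_index is not None and t.turn_index <= 2:
                    f = t.inward()
                    if f is not None:
                        flags.append(f)
        # a few-percent geometric floor: turns where neither direction can
        # reduce the angle to the inward vector
        assert np.mean(flags) > 0.93

    def test_closed_loop_recovery_of_programmed_bias(self):
        spec = bias_probe_spec(0.75, seed=19)
        cfg = SimConfig(dists=ParametricStateDistributions(spec),
                        model="WTSB_BC_TB", border_model=_border_model(spec),
                        seed=19, turn_style="split")
        arena = ArenaConfig()
        flags = []
        i = 0
        while len(flags) < 1000 and i < 250:
            res = simulate_fly(cfg, fly_id=i)
            i += 1
            for t in turn_geometries(res.segments, res.traj, arena):
                if t.turn_index is not None and t.turn_index <= 2:
                    f = t.inward()
                    if f is not None:
                        flags.append(f)
        assert np.mean(flags) == pytest.approx(0.75, abs=0.04)


class TestSelection:
    def _mk(self, arena, r_before, r_during, fly_id=0):
        n = arena.n_frames
        t = np.arange(n) / arena.fps
        n_before = int(np.sum(t < arena.light_on_s))
        r = np.concatenate([
            np.broadcast_to(np.asarray(r_before, float),
                            (n_before,)) if np.isscalar(r_before)
            else np.linspace(r_before[0], r_before[1], n_before),
            np.broadcast_to(np.asarray(r_during, float),
                            (n - n_before,)) if np.isscalar(r_during)
            else np.linspace(r_during[0], r_during[1], n - n_before),
        ])
        traj = Trajectory(t=t, x=r, y=np.zeros(n), theta=np.zeros(n))
        labels = np.full(n, "curved_walk", dtype=object)
        from flywalk.segmentation import first_entry_time
        return SimResult(traj=traj, labels=labels, fly_id=fly_id,
                         first_entry_time_s=first_entry_time(traj, arena))

    def test_toy_cohort_three_of_five_selected(self, arena):
        lo = 0.9 * arena.border_radius_mm - 1.0
        hi = 1.1 * arena.border_radius_mm + 1.0
        flies = [
            self._mk(arena, (lo, hi), (hi, lo), 0),   # ok
            self._mk(arena, (hi, lo), (hi, lo), 1),   # ok
            self._mk(arena, (lo, hi), (hi, lo), 2),   # ok
            self._mk(arena, lo, lo, 3),          # never leaves the light zone
            self._mk(arena, hi, hi, 4),          # never enters after light-on
        ]
        cfg = SimConfig(dists=_DegenerateDists(), seed=0)
        kept = select_flies(flies, cfg, empirical_first_entries=[400.0],
                            use_percentile_rule=True)
        assert sorted(r.fly_id for r in kept) == [0, 1, 2]
        assert not flies[3].selected and not flies[4].selected

    def test_percentile_rule_needs_reference(self, arena):
        cfg = SimConfig(dists=_DegenerateDists(), seed=0)
        with pytest.raises(ValueError):
            select_flies([], cfg, empirical_first_entries=None,
                         use_percentile_rule=True)

    def test_late_enterers_cut_by_percentile(self, arena):
        lo = 0.9 * arena.border_radius_mm - 1.0
        hi = 1.1 * arena.border_radius_mm + 1.0
        fly = self._mk(arena, (lo, hi), (hi, lo))
        cfg = SimConfig(dists=_DegenerateDists(), seed=0)
        fe = fly.first_entry_time_s
        kept = select_flies([fly], cfg, empirical_first_entries=[fe - 50.0])
        assert kept == []


class TestModelConfig:
    def test_bc_tb_requires_border_model(self, base_dists):
        with pytest.raises(ValueError):
            SimConfig(dists=base_dists, model="WTSB_BC_TB")

    def test_unknown_model_rejected(self, base_dists):
        with pytest.raises(ValueError):
            SimConfig(dists=base_dists, model="LEVY")
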