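import numpy as np
import pandas as pd
import pytest

from flywalk import ArenaConfig, GroundTruthSpec, generate_cohort
from flywalk.kinematics import compute_kinematics


@pytest.fixture(scope="session")
def arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture(scope="session")
def small_cohort(arena):
    """Ten noise-free flies with realistic state parameters (split turns)."""
    spec = GroundTruthSpec(seed=42, noise_sd_mm=0.0, turn_style="split")
    return generate_cohort(spec, n=10, build_segments=True)


@pytest.fixture(scope="session")
def interior_cohort(arena):
    """Slow flies that never reach the wall: walks, turns and stops only."""
    from dataclasses import replace

    from flywalk.synthetic_data import DEFAULT_SCENARIO_PARAMS

    params = {s: replace(p, walk_speed_median=0.8, walk_speed_sigma=0.15)
              for s, p in DEFAULT_SCENARIO_PARAMS.items()}
    spec = GroundTruthSpec(scenario_params=params, seed=17, noise_sd_mm=0.0,
                           turn_style="split")
    cohort = generate_cohort(spec, n=6, build_segments=True)
    return [r for r in cohort if not (r.labels == "boundary").any()]


@pytest.fixture(scope="session")
def pooled_segments(small_cohort):
    return pd.concat([r.segments for r in small_cohort], ignore_index=True)


@pytest.fixture(scope="session")
def cohort_kinematics(small_cohort, arena):
    return [compute_kinematics(r.traj, arena) for r in small_cohort]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
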