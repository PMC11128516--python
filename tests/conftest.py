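import numpy as np
import pytest

import qusmap as q


@pytest.fixture(scope="session")
def hk_table():
    """Default HK theory lookup table, shared across the whole suite."""
    return q.build_hk_lookup_table()


@pytest.fixture(scope="session")
def small_config():
    """A reduced frame geometry (same spacings as the default) for fast tests."""
    return q.AcquisitionConfig(n_samples=512, n_lines=128, lateral_extent_mm=20.0)


@pytest.fixture(scope="session")
def small_phantom_env(small_config, hk_table):
    """One small inclusion phantom frame: envelope + truth + its three maps."""
    spec = q.PhantomSpec(
        field_width_mm=small_config.lateral_extent_mm,
        field_depth_mm=small_config.depth_mm,
        background_density=2.0,
        inclusion_density=16.0,
        inclusion_center_mm=(10.0, 6.5),
        inclusion_diameter_mm=6.0,
    )
    rf = q.simulate_phantom_frame(spec, small_config, seed=1234)
    env = q.compute_envelope(rf)
    maps = q.compute_parametric_maps(env, hk_table)
    return env, maps


@pytest.fixture(scope="session")
def ci_experiment(hk_table):
    """Scaled three-type phantom study: 6 frames per type, 4 train / 2 test."""
    plan = q.ExperimentPlan(
        phantom_types=((2, 16), (2, 24), (2, 32)),
        frames_per_type=6,
        train_frames_per_type=4,
        master_seed=1,
    )
    return q.run_phantom_experiment(plan, table=hk_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240517)
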