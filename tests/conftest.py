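import numpy as np
import pytest

from qppfc import SynthConfig, make_atlas, simulate_cohort


def small_config(**overrides) -> SynthConfig:
    """Desk-scale study conditions used throughout the tests: a
    16x16x4 grid with four 2x2x2 homotopic block pairs."""
    base = dict(
        grid_dims=(16, 16, 4),
        n_roi_pairs=4,
        roi_block_voxels=(2, 2, 2),
        n_subjects=1,
        n_frames=300,
        network_r=0.3,
        global_amp=0.0,
        qpp_amp=0.0,
        seed=0,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def small_atlas():
    return make_atlas(small_config())


@pytest.fixture(scope="session")
def noise_dataset():
    """One pure-AR(1)-noise session (no network, global or events)."""
    cfg = small_config(network_r=0.0, seed=42)
    co = simulate_cohort(cfg, n_sessions=1)
    return co.datasets[(0, 0)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
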