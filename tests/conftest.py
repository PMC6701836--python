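import numpy as np
import pytest

from vsbias import BiasConfig, GridSpec, generate_dataset, synthetic_type_map


@pytest.fixture(scope="session")
def micro_config():
    """A small biased dataset: 4 targets in 2 families."""
    return BiasConfig(
        n_targets=4, n_families=2, actives_per_target=10, decoys_per_target=20,
        decoy_shift=2.0, family_share=0.5, intra_spread=0.4, seed=7,
    )


@pytest.fixture(scope="session")
def micro_targets(micro_config):
    return generate_dataset(micro_config)


@pytest.fixture(scope="session")
def type_map():
    return synthetic_type_map()


@pytest.fixture(scope="session")
def tiny_grid_spec():
    """8-voxel grid: the smallest edge the three-stage CNN accepts."""
    return GridSpec.synthetic(voxels_per_edge=8, resolution=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
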