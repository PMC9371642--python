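import numpy as np
import pytest

import connbench as cb


@pytest.fixture
def index4():
    return cb.build_edge_index(4)


@pytest.fixture
def index12():
    return cb.build_edge_index(12)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small generator spec (12 nodes, 3 communities, 80 subjects)."""
    index = cb.build_edge_index(12)
    partition = cb.equal_partition(12, 3)
    delta = cb.make_effect_map(index, partition, delta_within=-0.5,
                               between_mean=0.1, between_sd=0.1, seed=11)
    return cb.GeneratorSpec(index=index, partition=partition, delta=delta,
                            n_subjects=80, within_pair_noise_correlation=0.3,
                            seed=11)


@pytest.fixture(scope="session")
def tiny_population(tiny_spec):
    return cb.simulate_population(tiny_spec)
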