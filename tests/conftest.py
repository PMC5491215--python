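import numpy as np
import pytest

from netdendro import (NetworkLocation, SyntheticTreeSpec, build_network,
                       generate_dendrite)

# small trees keep the discretization oracles affordable
SMALL_SPEC = SyntheticTreeSpec(length_range=(30.0, 60.0),
                               branch_point_range=(2, 4),
                               branch_rate=0.08,
                               trunk_length_range=(3.0, 6.0),
                               step=2.0)

# mid-size trees for simulation/statistical tests
MID_SPEC = SyntheticTreeSpec(length_range=(400.0, 600.0),
                             branch_point_range=(2, 8),
                             branch_rate=1.0 / 90.0,
                             trunk_length_range=(15.0, 40.0),
                             step=3.0)


@pytest.fixture
def single_segment():
    """A single straight segment of length 10, rooted at one end."""
    return build_network([(0, 0, 0), (10, 0, 0)], [(0, 1)], root_vertex=0)


@pytest.fixture
def y_tree():
    """Trunk of length 4 with two branches of length 3 each (|L| = 10)."""
    return build_network([(0, 0, 0), (0, 0, 4), (3, 0, 4), (0, 3, 4)],
                         [(0, 1), (1, 2), (1, 3)], root_vertex=0)


@pytest.fixture
def small_tree_factory():
    def make(seed):
        return generate_dendrite(SMALL_SPEC, seed=seed)

    return make


@pytest.fixture
def mid_tree():
    return generate_dendrite(MID_SPEC, seed=20240)


def random_location(net, rng):
    s = int(rng.integers(net.n_segments))
    return NetworkLocation(s, float(rng.uniform(0.0, net.lengths[s])))


def random_locations(net, rng, k):
    return [random_location(net, rng) for _ in range(k)]


def rigid_transform(coords, rng):
    """A random proper rotation plus translation of vertex coordinates."""
    from scipy.stats import special_ortho_group

    q = special_ortho_group.rvs(3, random_state=np.random.RandomState(
        int(rng.integers(2**31 - 1))))
    shift = rng.uniform(-50, 50, size=3)
    return coords @ q.T + shift
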