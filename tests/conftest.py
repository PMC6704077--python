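import numpy as np
import pytest

import mscope as m


@pytest.fixture(scope="session")
def small_head():
    """A 4,000-node synthetic head shared by read-only tests."""
    return m.build_head_model(4000, seed=11)


@pytest.fixture(scope="session")
def layout():
    return m.layout_electrodes()


@pytest.fixture()
def rng():
    return np.random.default_rng(202)


def random_labeled_instance(rng, n):
    """A random cloud + labels + field for oracle comparisons."""
    coords = rng.normal(0.0, 40.0, size=(n, 3))
    ids = rng.permutation(np.arange(1, n + 1))
    cloud = m.NodeCloud(node_id=ids, coords=coords, space="talairach")
    labels = m.label_nodes(cloud, m.SyntheticAtlas())
    values = rng.gamma(2.0, 0.1, size=n)
    field = m.FieldVector(node_id=ids, value=values, montage_name="rand")
    return cloud, labels, field
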