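import pytest

from celldiff3d import (
    TransitionKernel,
    example_networks,
    find_attractors,
    label_attractors,
    myeloid_demo_network,
    myeloid_expression_patterns,
    myeloid_lineage_tree,
)


@pytest.fixture(scope="session")
def nets():
    """Micro example networks plus the 11-gene myeloid demo."""
    return example_networks()


@pytest.fixture(scope="session")
def demo_net():
    return myeloid_demo_network()


@pytest.fixture(scope="session")
def demo_attractors(demo_net):
    aset = find_attractors(demo_net)
    return label_attractors(aset, myeloid_expression_patterns(), demo_net)


@pytest.fixture(scope="session")
def demo_kernel(demo_net):
    return TransitionKernel(demo_net, 0.01)


@pytest.fixture(scope="session")
def lineage_tree():
    return myeloid_lineage_tree()
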