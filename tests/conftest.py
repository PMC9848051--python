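import numpy as np
import pytest

from neuminer.swc import SwcNode, SwcTree
from neuminer.synthetic import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic default scene shared by read-only tests."""
    return generate_scene(SceneConfig(rng_seed=11))


@pytest.fixture
def straight_tree():
    """Soma at (10,10,10) with a straight x-axis neurite of 10 nodes."""
    nodes = [SwcNode(1, 1, 10, 10, 10, 3, -1)]
    for i in range(1, 11):
        nodes.append(SwcNode(i + 1, 3, 10 + i, 10, 10, 1, i))
    return SwcTree(nodes)


def random_tree(rng, n_nodes=40, spread=30.0):
    """Random connected tree: each node attaches to a random earlier node."""
    nodes = [SwcNode(1, 1, spread, spread, spread, 2, -1)]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        px, py, pz = nodes[parent - 1].x, nodes[parent - 1].y, nodes[parent - 1].z
        step = rng.normal(0, 2.0, size=3)
        nodes.append(SwcNode(i, 3, px + step[0], py + step[1], pz + step[2],
                             1.0, parent))
    return SwcTree(nodes)
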