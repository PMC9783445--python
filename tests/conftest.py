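import numpy as np
import pytest

from osteophylo.trees import read_tree
from osteophylo.synthetic import simulate_tree
from osteophylo.volumes import VoxelVolume


@pytest.fixture
def three_tip_tree():
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tip():
    return read_tree("(((A:1,B:1):1,(C:1,D:1):1):1,E:3);")


def small_fixture_trees():
    """Hand-written 4-6 tip trees covering balanced/caterpillar/non-
    ultrametric shapes, for exact-oracle comparisons."""
    return [
        "((A:1,B:1):1,(C:1,D:1):1);",
        "(((A:1,B:1):1,C:2):1,D:3);",
        "((((A:1,B:1):1,C:2):1,D:3):1,E:4);",
        "(((A:2,B:1.5):1,(C:0.7,D:2):1.3):1,(E:2.2,F:3):1);",
        "((A:0.5,B:1):1,(C:2,D:1.2):0.3);",
    ]


@pytest.fixture(params=small_fixture_trees())
def fixture_tree(request):
    return read_tree(request.param)


@pytest.fixture
def hollow_tube():
    """Binary hollow tube: outer radius 20, inner radius 10 voxels."""
    ax = np.arange(64)
    d2 = (ax[:, None] - 32) ** 2 + (ax[None, :] - 32) ** 2
    ring = (d2 <= 400) & (d2 > 100)
    grid = np.broadcast_to(ring, (20, 64, 64)).copy().astype(np.uint8)
    return VoxelVolume(grid, 0.01, binary=True)


def random_trees(n_trees, n_tips, seed0=0, fossil_tips=0):
    return [
        simulate_tree(n_tips, seed=seed0 + k, fossil_tips=fossil_tips)
        for k in range(n_trees)
    ]
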