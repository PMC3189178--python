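import numpy as np
import pytest

from circlin import GuideTree, OrthologPair, OrthologPairSet


def make_pair_set(y_ranks, O, O_x=None):
    """Pair set with x_ranks 1..n and the given target ranks."""
    pairs = [
        OrthologPair(f"a{i}", f"b{i}", i + 1, int(y), 1e-50)
        for i, y in enumerate(y_ranks)
    ]
    return OrthologPairSet(pairs=pairs, O_x=O_x or max(len(y_ranks), O), O_y=O)


def brute_force_C(y_ranks, O, wrap):
    """First-principles C: walk the circle stepwise in both directions."""

    def walk(a, b):
        fwd = 0
        p = a
        while p != b:
            p = p % O + 1
            fwd += 1
        return min(fwd, O - fwd)

    ys = list(y_ranks)
    neighbours = list(zip(ys, ys[1:]))
    if wrap:
        neighbours.append((ys[-1], ys[0]))
    return sum(walk(a, b) for a, b in neighbours) / O


@pytest.fixture
def five_leaf_tree():
    return GuideTree.from_newick("((A:0.3,B:0.7):0.5,(C:0.2,(D:0.4,E:0.1):0.6):0.3);")


@pytest.fixture
def eight_leaf_tree():
    return GuideTree.from_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
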