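import numpy as np
import pytest

from phylorates.tree_io import Node, Tree


def random_binary_tree(rng: np.random.Generator, n_leaves: int,
                       scale: float = 0.5) -> Tree:
    """Random rooted binary topology with Exp(scale) branch lengths."""
    nodes = [Node(f"t{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = Node()
        for child in (left, right):
            child.length = float(rng.exponential(scale)) + 1e-3
            parent.add_child(child)
        nodes.append(parent)
    return Tree(nodes[0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240927)


@pytest.fixture
def tree4():
    from phylorates import parse_newick
    return parse_newick("((A:0.3,B:0.4):0.2,(C:0.25,D:0.35):0.15);")


@pytest.fixture
def tree5():
    from phylorates import parse_newick
    return parse_newick(
        "(((A:0.2,B:0.3):0.15,C:0.4):0.1,(D:0.25,E:0.35):0.2);")


@pytest.fixture
def tree10():
    from phylorates import parse_newick
    return parse_newick(
        "(((A:0.2,B:0.3):0.1,((C:0.15,D:0.25):0.2,E:0.35):0.1):0.15,"
        "((F:0.3,G:0.2):0.25,(H:0.15,(I:0.2,J:0.3):0.1):0.2):0.1);")
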