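import numpy as np
import pytest

from cladepath.trees import Tree


def make_random_tree(rng: np.random.Generator, n_tips: int, min_len=0.05, max_len=2.0) -> Tree:
    """Random binary rooted tree: tips joined pairwise in random order,
    branch lengths uniform.  Independent of the package's simulators."""
    parent = [-1] * (2 * n_tips - 1)
    children = [[] for _ in range(2 * n_tips - 1)]
    lengths = [0.0] * (2 * n_tips - 1)
    labels: list = [None] * (2 * n_tips - 1)
    nxt = 0
    groups = []
    for i in range(n_tips):
        labels[nxt] = f"t{i+1}"
        groups.append(nxt)
        nxt += 1
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        a, b = groups[j], groups[i]
        p = nxt
        nxt += 1
        parent[a] = parent[b] = p
        children[p] = [a, b]
        lengths[a] = float(rng.uniform(min_len, max_len))
        lengths[b] = float(rng.uniform(min_len, max_len))
        groups[i] = p
        groups.pop(j)
    # reindex so the root is node 0 (Tree requires valid parent pointers only)
    return Tree(parent, children, lengths, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def random_tree_factory():
    return make_random_tree


@pytest.fixture
def small_tree():
    from cladepath.trees import parse_newick

    return parse_newick("((A:1,B:1):1,C:2):0;")
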