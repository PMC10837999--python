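import numpy as np
import pytest

import microimmune as mi


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic cohort shared by read-only tests."""
    cfg = mi.SynthConfig(seed=7, n_per_cell=6, n_features=30)
    return mi.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_tree(n_leaves: int, rng: np.random.Generator):
    """Random rooted binary tree with uniform(0.1, 2) branch lengths."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"f{i}", length=float(rng.uniform(0.1, 2)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.1, 2)) if len(nodes) else None
        nodes.append(parent)
    return nodes[0]


def unifrac_bruteforce(table, tree, normalized=False):
    """Per-branch descendant-set enumeration oracle for weighted UniFrac."""
    ids = list(table.index)
    n = len(ids)
    props = table.div(table.sum(axis=1), axis=0)
    branches = []
    for node in tree.traverse(include_self=False):
        leaves = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        branches.append((node.length or 0.0, leaves))
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 0.0
            norm = 0.0
            for length, leaves in branches:
                pa = sum(props.loc[ids[i], f] for f in leaves if f in props.columns)
                pb = sum(props.loc[ids[j], f] for f in leaves if f in props.columns)
                d += length * abs(pa - pb)
                norm += length * (pa + pb)
            out[i, j] = out[j, i] = d / norm if normalized else d
    return out
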