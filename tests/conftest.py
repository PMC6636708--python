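import numpy as np
import pytest

from phylorates import simulate
from phylorates.tree_io import DatedTree, node_ages


@pytest.fixture()
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture()
def three_tip_tree():
    from phylorates.tree_io import read_newick

    return read_newick("((A:1,B:1):1,C:2);")[0]


def yule_tree(rng, lam=0.001, max_time=3000.0, min_tips=2) -> DatedTree:
    """A conditioned pure-birth tree drawn from the shared generator."""
    params = simulate.BDParams(lambda0=lam, max_time=max_time)
    res = simulate.simulate_tree(params, rng=rng, min_tips=min_tips)
    assert res.tree is not None
    return res.tree


def stab_counts(tree: DatedTree, times) -> np.ndarray:
    """Independent interval-stabbing oracle for the LTT step function.

    Counts the edges whose [child age, parent age) span contains each query
    time.  Valid for generic times (not exactly at a node age), where the tie
    convention is irrelevant.
    """
    ages = node_ages(tree)
    spans = []
    for node in tree.root.preorder():
        for child in node.children:
            spans.append((ages[child], ages[node]))
    times = np.asarray(times, dtype=float)
    out = np.zeros(times.size, dtype=int)
    for lo, hi in spans:
        out += (times >= lo) & (times < hi)
    return out


def tip_depths(tree: DatedTree) -> dict[str, float]:
    """Root-to-tip path lengths computed by naive recursion (oracle)."""
    out: dict[str, float] = {}

    def walk(node, depth):
        if node.is_leaf:
            out[node.label] = depth
        for child in node.children:
            walk(child, depth + child.length)

    walk(tree.root, 0.0)
    return out
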