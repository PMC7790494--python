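import pytest

from ccnkit.builder import build_taxonomy
from ccnkit.dendrogram import DendNode
from ccnkit.fixtures import MTG_DEFAULTS, simulate_taxonomy


def balanced_tree(labels, start=1, id_prefix=""):
    """Balanced binary tree whose leaves carry `labels` at positions start.."""

    def build(lo, hi):
        if lo == hi:
            return DendNode(f"{id_prefix}L{lo}", original_label=labels[lo - start])
        mid = (lo + hi) // 2
        node = DendNode(f"{id_prefix}N{lo}_{hi}")
        node.children = [build(lo, mid), build(mid + 1, hi)]
        return node

    return build(start, start + len(labels) - 1)


def caterpillar_tree(labels):
    """Left caterpillar: ((((1,2),3),4)...)."""
    node = DendNode("cL1", original_label=labels[0])
    for i, label in enumerate(labels[1:], start=2):
        parent = DendNode(f"cN{i}")
        parent.children = [node, DendNode(f"cL{i}", original_label=label)]
        node = parent
    return node


def random_tree(n_leaves, seed, branching=2):
    root, _ = simulate_taxonomy(n_leaves, branching=branching, cells_per_leaf=0, seed=seed)
    return root


@pytest.fixture
def mtg_like_root():
    """A 75-leaf taxonomy tree whose first six types sit under one node,
    mirroring the human MTG layout (LAMP5/PAX6 branch first)."""
    first_six = [
        "Inh L1-2 PAX6 CDH12",
        "Inh L1-4 LAMP5 LCP2",
        "Inh L1 LAMP5 A",
        "Inh L1 LAMP5 B",
        "Inh L1-2 PAX6 A",
        "Inh L1-2 PAX6 B",
    ]
    rest = [f"Cluster {i:02d}" for i in range(7, 76)]
    root = DendNode("root")
    root.children = [
        balanced_tree(first_six, start=1, id_prefix="a"),
        balanced_tree(rest, start=7, id_prefix="b"),
    ]
    return root


@pytest.fixture
def mtg_taxonomy(mtg_like_root):
    return build_taxonomy(MTG_DEFAULTS, mtg_like_root)
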