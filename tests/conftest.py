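"""Shared fixtures: small species trees, the hand-built worked example, a
random gene-tree generator, and independent brute-force oracles for
reconciliation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import wgdkit as w
from wgdkit.treecore import TreeNode

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# Species trees


@pytest.fixture
def species_ab():
    return w.parse_newick("(a:10,b:10);", role="species")


@pytest.fixture
def species_abc():
    return w.parse_newick("((a:10,b:10):10,c:20);", role="species")


@pytest.fixture
def species_abcd_marked():
    """Four species; an older WGD above the (a,b) ancestor and a younger WGD
    on the terminal branch to a — two nested events on one trajectory."""
    return w.parse_newick(
        "((a[&&NHX:W=1:T=15]:30,b:30)[&&NHX:W=0:T=45]:30,(c:30,d:30):30);",
        role="species",
    )


@pytest.fixture
def worked_example(species_abcd_marked):
    """The single-family retention scenario: the older duplicate pair (A1,
    A2) both survive; after the younger event A1's copies survive and A2's
    copy is lost.  Gene tree (((a1,a2),b1),(a3,b2)) with an outgroup clade
    (c1,d1)."""
    gene = w.parse_newick("((((a1,a2),b1),(a3,b2)),(c1,d1));")
    w.assign_species(gene, "suffix")
    return species_abcd_marked, gene


# ---------------------------------------------------------------------------
# Random gene trees


def _random_gene_tree(rng: np.random.Generator, n_leaves: int,
                      species_pool: list[str]) -> TreeNode:
    nodes = []
    for i in range(n_leaves):
        sp = species_pool[rng.integers(0, len(species_pool))]
        leaf = TreeNode(label=f"{sp}{i + 1}")
        leaf.species = sp
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[j:j + 1] = []
        nodes[i] = parent
    return nodes[0]


@pytest.fixture
def random_gene_tree():
    return _random_gene_tree


# ---------------------------------------------------------------------------
# Brute-force reconciliation oracle (independent of the implementation: maps
# by scanning all species nodes for the smallest containing leaf set, counts
# losses by explicit path enumeration)


def _oracle_reconcile(gene_root: TreeNode, species_root: TreeNode):
    sp_nodes = list(species_root.postorder())
    leafset = {
        id(n): frozenset(l.label for l in n.leaves()) for n in sp_nodes
    }

    def smallest_containing(species: frozenset) -> TreeNode:
        best = None
        for n in sp_nodes:
            if species <= leafset[id(n)]:
                if best is None or len(leafset[id(n)]) < len(leafset[id(best)]):
                    best = n
        assert best is not None
        return best

    def ancestors_inclusive(node: TreeNode) -> list[TreeNode]:
        out = [node]
        while out[-1].parent is not None:
            out.append(out[-1].parent)
        return out

    mapping: dict[int, TreeNode] = {}
    gene_species: dict[int, frozenset] = {}
    dup = 0
    loss = 0
    for g in gene_root.postorder():
        if g.is_leaf:
            gene_species[id(g)] = (
                g.loss_species if g.is_loss else frozenset([g.species])
            )
        else:
            gene_species[id(g)] = frozenset().union(
                *(gene_species[id(c)] for c in g.children)
            )
        mapping[id(g)] = smallest_containing(gene_species[id(g)])
    for g in gene_root.postorder():
        if g.is_leaf:
            continue
        is_dup = any(mapping[id(c)] is mapping[id(g)] for c in g.children)
        dup += is_dup
        for c in g.children:
            path = ancestors_inclusive(mapping[id(c)])
            gap = path.index(mapping[id(g)])
            loss += gap if is_dup else gap - 1
    return dup, loss


@pytest.fixture
def oracle_reconcile():
    return _oracle_reconcile


# ---------------------------------------------------------------------------
# Structural tree equality (for round-trip tests)


def _tree_equal(a: TreeNode, b: TreeNode) -> bool:
    if a.label != b.label or a.length != b.length:
        return False
    if (a.mark is None) != (b.mark is None):
        return False
    if a.mark is not None and (
        a.mark.event_index != b.mark.event_index or a.mark.time != b.mark.time
    ):
        return False
    if a.wgd_labels != b.wgd_labels:
        return False
    if a.is_loss != b.is_loss or a.loss_species != b.loss_species:
        return False
    if len(a.children) != len(b.children):
        return False
    return all(_tree_equal(x, y) for x, y in zip(a.children, b.children))


@pytest.fixture
def tree_equal():
    return _tree_equal
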