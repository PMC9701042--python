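"""Gene-tree/species-tree reconciliation by LCA mapping.

Implements the classic most-parsimonious embedding of a gene tree into a
species tree: every gene node is mapped to the last common ancestor (in the
species tree) of the species of its leaves; a node is a duplication exactly
when its mapping coincides with a child's mapping; losses are counted along
the gaps the mapping skips over.  On top of that sit the three operations the
WGD pipeline needs: exhaustive duplication+loss-minimizing rooting of
unrooted input trees, iterative splitting of duplication-rooted trees, and
explicit insertion of loss leaves (each carrying the species set of the lost
clade) so that downstream species-set bookkeeping sees lost lineages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import LeafMappingError, TreeValidationError
from .treecore import TreeNode, clade_species

__all__ = [
    "ReconciliationResult",
    "lca_reconcile",
    "root_by_min_dl",
    "split_dup_root",
    "insert_loss_leaves",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"


@dataclass
class ReconciliationResult:
    """A rooted gene tree with duplication/speciation labels and loss counts.

    ``root_edge_id`` identifies the rooting edge chosen by
    :func:`root_by_min_dl` (post-order edge index of the unrooted input);
    ``None`` when the input rooting was kept.
    """

    root: TreeNode
    dup_count: int
    loss_count: int
    root_edge_id: Optional[int] = None

    @property
    def score(self) -> int:
        return self.dup_count + self.loss_count


class _SpeciesIndex:
    """Parent/depth tables for constant-size LCA walks on a species tree."""

    def __init__(self, species_root: TreeNode):
        self.root = species_root
        self.depth: dict[int, int] = {}
        self.by_name: dict[str, TreeNode] = {}
        for node in species_root.preorder():
            self.depth[id(node)] = (
                0 if node.parent is None else self.depth[id(node.parent)] + 1
            )
            if node.is_leaf:
                self.by_name[node.label] = node

    def lca(self, u: TreeNode, v: TreeNode) -> TreeNode:
        du, dv = self.depth[id(u)], self.depth[id(v)]
        while du > dv:
            u = u.parent
            du -= 1
        while dv > du:
            v = v.parent
            dv -= 1
        while u is not v:
            u, v = u.parent, v.parent
        return u

    def leaf(self, species: str) -> TreeNode:
        try:
            return self.by_name[species]
        except KeyError:
            raise LeafMappingError(
                f"species {species!r} is not a leaf of the species tree"
            ) from None


def _map_leaf(leaf: TreeNode, index: _SpeciesIndex) -> TreeNode:
    if leaf.is_loss:
        # a loss leaf stands for a whole pruned clade
        nodes = [index.leaf(sp) for sp in leaf.loss_species]
        m = nodes[0]
        for other in nodes[1:]:
            m = index.lca(m, other)
        return m
    if leaf.species is None:
        raise LeafMappingError(
            f"gene leaf {leaf.label!r} has no species assigned; call "
            "assign_species first"
        )
    return index.leaf(leaf.species)


def lca_reconcile(
    gene_root: TreeNode, species_root: TreeNode
) -> ReconciliationResult:
    """Label a rooted gene tree by LCA mapping against the species tree.

    Mutates the gene tree in place: sets ``mapping`` on every node, ``event``
    (speciation/duplication) on internal nodes, and ``species_set`` (observed
    plus loss-leaf species) everywhere.
    """
    index = _SpeciesIndex(species_root)
    dup_count = 0
    loss_count = 0
    for node in gene_root.postorder():
        if node.is_leaf:
            node.mapping = _map_leaf(node, index)
            node.event = None
            node.species_set = (
                node.loss_species if node.is_loss else frozenset([node.species])
            )
            continue
        left, right = node.children
        node.mapping = index.lca(left.mapping, right.mapping)
        node.species_set = left.species_set | right.species_set
        is_dup = node.mapping is left.mapping or node.mapping is right.mapping
        node.event = DUPLICATION if is_dup else SPECIATION
        if is_dup:
            dup_count += 1
        d_node = index.depth[id(node.mapping)]
        for child in (left, right):
            gap = index.depth[id(child.mapping)] - d_node
            loss_count += gap if is_dup else gap - 1
    return ReconciliationResult(gene_root, dup_count, loss_count)


# ---------------------------------------------------------------------------
# Rooting


def _strip(node: TreeNode) -> TreeNode:
    """A topology+leaf-payload copy of a gene (sub)tree."""
    copy = TreeNode(label=node.label, length=node.length)
    copy.species = node.species
    copy.is_loss = node.is_loss
    copy.loss_species = node.loss_species
    for child in node.children:
        copy.add_child(_strip(child))
    return copy


def _unrooted_adjacency(root: TreeNode) -> dict[int, list[TreeNode]]:
    """Adjacency of the unrooted tree underlying a rooted representation.

    A binary root of degree 2 is suppressed (its two edges become one)."""
    adj: dict[int, list[TreeNode]] = {}
    nodes = list(root.postorder())
    for node in nodes:
        adj.setdefault(id(node), [])
    for node in nodes:
        if node.parent is not None:
            adj[id(node)].append(node.parent)
            adj[id(node.parent)].append(node)
    if len(root.children) == 2:
        a, b = root.children
        adj[id(a)] = [x for x in adj[id(a)] if x is not root] + [b]
        adj[id(b)] = [x for x in adj[id(b)] if x is not root] + [a]
        del adj[id(root)]
    return adj


def _orient(
    node: TreeNode, away_from: TreeNode, adj: dict[int, list[TreeNode]]
) -> TreeNode:
    copy = TreeNode(label=node.label)
    copy.species = node.species
    copy.is_loss = node.is_loss
    copy.loss_species = node.loss_species
    for nb in adj[id(node)]:
        if nb is not away_from:
            copy.add_child(_orient(nb, node, adj))
    return copy


def _enumerate_edges(root: TreeNode) -> list[tuple[TreeNode, TreeNode]]:
    """Unrooted edges in a canonical (post-order) ordering."""
    adj = _unrooted_adjacency(root)
    edges: list[tuple[TreeNode, TreeNode]] = []
    seen: set[frozenset[int]] = set()
    for node in root.postorder():
        if id(node) not in adj:
            continue
        for nb in adj[id(node)]:
            key = frozenset((id(node), id(nb)))
            if key not in seen:
                seen.add(key)
                edges.append((node, nb))
    return edges


def root_on_edge(
    gene_tree: TreeNode, edge: tuple[TreeNode, TreeNode]
) -> TreeNode:
    """Build a rooted copy of the unrooted gene tree with the root placed on
    ``edge``.  Branch lengths are dropped (reconciliation ignores them)."""
    adj = _unrooted_adjacency(gene_tree)
    u, v = edge
    root = TreeNode()
    root.add_child(_orient(u, v, adj))
    root.add_child(_orient(v, u, adj))
    return root


def root_by_min_dl(
    gene_tree: TreeNode, species_root: TreeNode
) -> ReconciliationResult:
    """Root an unrooted gene tree on the edge minimizing duplications+losses.

    Every edge of the unrooted tree is tried; ties break to the lowest
    canonical edge index, making the choice deterministic.  Trees with fewer
    than 3 leaves have a single rooting, which is returned as-is.
    """
    leaves = gene_tree.leaves()
    if len(leaves) < 3:
        return lca_reconcile(_strip(gene_tree), species_root)
    best: Optional[ReconciliationResult] = None
    for edge_id, edge in enumerate(_enumerate_edges(gene_tree)):
        rooted = root_on_edge(gene_tree, edge)
        result = lca_reconcile(rooted, species_root)
        result.root_edge_id = edge_id
        if best is None or result.score < best.score:
            best = result
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Splitting duplication-rooted trees


def split_dup_root(
    result: ReconciliationResult, species_root: TreeNode
) -> list[ReconciliationResult]:
    """Split trees whose root is a duplication until every root is a
    speciation event (or the tree covers a single species).

    The duplication root itself is discarded: a root duplication predates the
    species-tree root, hence predates every WGD mark, so no placement signal
    is lost.
    """
    out: list[ReconciliationResult] = []
    queue = [result]
    while queue:
        res = queue.pop()
        root = res.root
        multi_species = len(root.species_set or _species_set(root)) > 1
        if root.event == DUPLICATION and multi_species:
            for child in root.children:
                child.parent = None
                queue.append(lca_reconcile(child, species_root))
        else:
            out.append(res)
    out.reverse()
    return out


def _species_set(root: TreeNode) -> frozenset[str]:
    out: set[str] = set()
    for leaf in root.leaves():
        if leaf.is_loss:
            out |= leaf.loss_species
        elif leaf.species is not None:
            out.add(leaf.species)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Loss leaves


def _make_loss_leaf(clade_root: TreeNode) -> TreeNode:
    species = clade_species(clade_root)
    leaf = TreeNode(label="LOSS", length=0.0)
    leaf.is_loss = True
    leaf.loss_species = species
    leaf.species_set = species
    leaf.mapping = clade_root
    return leaf


def insert_loss_leaves(result: ReconciliationResult) -> TreeNode:
    """Materialize inferred losses as explicit leaves, in place.

    For every gene edge whose child mapping skips species-tree nodes, one loss
    leaf per skipped node is inserted, carrying the species set of the pruned
    sibling clade.  Afterwards every node's ``species_set`` (observed + lost)
    equals the full species set of its species-tree mapping's clade, which is
    what the WGD candidate test relies on.
    """
    root = result.root
    n_inserted = 0
    for node in list(root.postorder()):
        if node.is_leaf:
            continue
        is_dup = node.event == DUPLICATION
        for child in list(node.children):
            path = [child.mapping]
            while path[-1] is not node.mapping:
                path.append(path[-1].parent)
            path.reverse()  # node.mapping .. child.mapping, top-down
            steps = path[:-1] if is_dup else path[1:-1]
            attach_parent = node
            attach_child = child
            for sp_node in steps:
                # the species child off the path toward child.mapping is lost
                on_path = path[path.index(sp_node) + 1]
                off_path = (
                    sp_node.children[1]
                    if sp_node.children[0] is on_path
                    else sp_node.children[0]
                )
                new = TreeNode(length=0.0)
                new.event = SPECIATION
                new.mapping = sp_node
                idx = attach_parent.children.index(attach_child)
                attach_parent.children[idx] = new
                new.parent = attach_parent
                new.add_child(attach_child)
                new.add_child(_make_loss_leaf(off_path))
                n_inserted += 1
                attach_parent = new
    if n_inserted != result.loss_count:
        raise TreeValidationError(
            f"inserted {n_inserted} loss leaves but reconciliation counted "
            f"{result.loss_count} losses"
        )
    # refresh species sets bottom-up
    for node in root.postorder():
        if node.is_leaf:
            node.species_set = (
                node.loss_species if node.is_loss else frozenset([node.species])
            )
        else:
            node.species_set = frozenset().union(
                *(c.species_set for c in node.children)
            )
    return root
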