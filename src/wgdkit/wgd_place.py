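"""Mapping species-tree WGD events onto reconciled gene trees.

Each whole-genome duplication marked on the species tree is located on a gene
tree by descending from the gene root to the most recent node(s) whose
species set (observed leaves plus loss leaves) equals the species set of the
clade directly below the event.  A candidate that is a duplication node is
labeled "present" (the duplicate survived in this family); a candidate that
is not is labeled "missing" (the duplicate was lost).  A duplication whose
two children are themselves duplications is interpreted as a small-scale
duplication (SSD) that predates the WGD, and the event descends onto both
children — the most parsimonious reading, which minimizes the number of
duplications attributed to SSD.  Ties go to the node closer to the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import TreeValidationError
from .reconcile import (
    DUPLICATION,
    insert_loss_leaves,
    root_by_min_dl,
    split_dup_root,
)
from .treecore import (
    MISSING,
    PRESENT,
    TreeNode,
    WGDLabel,
    WGDMark,
    clade_species,
    collect_marks,
)

__all__ = [
    "PlacementResult",
    "map_event_candidates",
    "place_event",
    "place_all",
    "place_unrooted",
]


@dataclass
class PlacementResult:
    """WGD labels for one gene tree.

    ``labels`` maps event index -> list of (node, status) in the order the
    nodes were labeled; ``ssd_count`` is the number of duplication nodes left
    unexplained by any WGD (attributed to small-scale duplication).
    """

    root: TreeNode
    labels: dict[int, list[tuple[TreeNode, str]]] = field(default_factory=dict)
    ssd_count: int = 0
    dup_count: int = 0

    def labeled_nodes(self, event_index: int) -> list[tuple[TreeNode, str]]:
        return self.labels.get(event_index, [])

    def all_labels(self) -> list[tuple[int, TreeNode, str]]:
        return [
            (evt, node, status)
            for evt, pairs in sorted(self.labels.items())
            for node, status in pairs
        ]


def _relevant_leaf_count(node: TreeNode, target: frozenset[str]) -> int:
    """Number of leaves under ``node`` carrying at least one target species
    (loss leaves count through their pruned-clade species set)."""
    count = 0
    for leaf in node.leaves():
        if leaf.species_set & target:
            count += 1
    return count


def map_event_candidates(s: TreeNode, g: TreeNode) -> list[TreeNode]:
    """Most recent gene nodes whose species set equals the clade below ``s``.

    ``s`` is the species-tree node directly after (below) the WGD event;
    ``g`` is a node of a reconciled gene tree with loss leaves inserted and
    ``species_set`` annotated.  Descends to the LCA of all leaves carrying
    species of the clade; whenever that LCA still holds species outside the
    clade it is a duplication predating the WGD, and the search recurses into
    both children.  Returns ``[]`` when no species of the clade occurs under
    ``g`` (the family does not span the event on this lineage).
    """
    target = clade_species(s)
    if g.species_set is None:
        raise TreeValidationError(
            "gene tree lacks species_set annotations; reconcile (and insert "
            "loss leaves) before placement"
        )
    return _find(g, target)


def _find(node: TreeNode, target: frozenset[str]) -> list[TreeNode]:
    total = _relevant_leaf_count(node, target)
    if total == 0:
        return []
    # descend to the LCA of the relevant leaves
    while not node.is_leaf:
        for child in node.children:
            if _relevant_leaf_count(child, target) == total:
                node = child
                break
        else:
            break
    sset = node.species_set
    if sset == target:
        return [node]
    if target < sset:
        # duplication predating the WGD: the event may map to both copies
        out: list[TreeNode] = []
        for child in node.children:
            out.extend(_find(child, target))
        return out
    # the family only samples part of the clade and nothing marks the rest
    # as lost here: the event predates this (sub)tree's root
    return []


def place_event(n: TreeNode, event_index: int) -> list[tuple[TreeNode, str]]:
    """Apply the labeling rule to one candidate node.

    - not a duplication: the duplicate was lost -> (n, missing);
    - duplication, children not both duplications: -> (n, present);
    - duplication with two duplication children: the node itself is an SSD
      that predates the WGD; both children get (present) labels.

    Loss leaves are never labeled (they only support the species-set test).
    Returns the emitted (node, status) pairs and records them on the nodes.
    """
    if n.is_loss:
        return []
    if n.event != DUPLICATION:
        emitted = [(n, MISSING)]
    elif all(c.event == DUPLICATION for c in n.children):
        emitted = [(c, PRESENT) for c in n.children]
    else:
        emitted = [(n, PRESENT)]
    for node, status in emitted:
        node.wgd_labels.append(WGDLabel(event_index, status))
    return emitted


def place_all(gene_root: TreeNode, species_root: TreeNode) -> PlacementResult:
    """Place every marked WGD event on one reconciled gene tree.

    Events are processed oldest first.  The gene tree must be speciation-
    rooted (or single-copy), reconciled, and have loss leaves inserted.
    """
    result = PlacementResult(root=gene_root)
    result.dup_count = sum(
        1 for n in gene_root.postorder() if n.event == DUPLICATION
    )
    for mark in collect_marks(species_root):
        candidates = map_event_candidates(mark.node, gene_root)
        emitted: list[tuple[TreeNode, str]] = []
        for cand in candidates:
            emitted.extend(place_event(cand, mark.event_index))
        if emitted:
            result.labels[mark.event_index] = emitted
    present_dups = {
        id(node)
        for pairs in result.labels.values()
        for node, status in pairs
        if status == PRESENT
    }
    result.ssd_count = result.dup_count - len(present_dups)
    return result


def place_unrooted(
    gene_tree: TreeNode, species_root: TreeNode
) -> list[PlacementResult]:
    """Full placement pipeline for one raw gene tree (species already
    assigned to leaves): duplication+loss-minimizing rooting, iterative
    splitting of duplication roots, loss-leaf insertion, event placement.
    Returns one PlacementResult per speciation-rooted part."""
    rooted = root_by_min_dl(gene_tree, species_root)
    parts = split_dup_root(rooted, species_root)
    out = []
    for part in parts:
        insert_loss_leaves(part)
        out.append(place_all(part.root, species_root))
    return out
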