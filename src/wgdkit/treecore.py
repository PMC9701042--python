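"""Tree data model, Newick/NHX input and output, species-naming conventions,
and discovery of nested WGD event pairs on an annotated species tree.

The toolkit works on rooted binary trees.  A species tree is time-calibrated
(branch lengths in millions of years, ultrametric) and may carry
whole-genome-duplication marks as NHX comments of the form
``[&&NHX:W=<event index>:T=<time MYA>]`` attached to the child node of the
duplicated branch.  Gene-tree leaves encode their species in the leaf label;
three naming conventions are supported (trailing integer, delimiter field,
explicit map).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Optional, Sequence, Union

import dendropy

from .errors import LeafMappingError, NewickParseError, TreeValidationError

__all__ = [
    "TreeNode",
    "WGDLabel",
    "WGDMark",
    "EventPair",
    "parse_newick",
    "write_newick",
    "read_gene_trees",
    "species_of_leaf",
    "assign_species",
    "annotate_ages",
    "collect_marks",
    "find_event_pairs",
    "clade_species",
]

#: status constants for WGD labels on gene-tree nodes
PRESENT = "present"
MISSING = "missing"

ULTRAMETRIC_TOL = 1e-6  # MY; tolerance for root-to-tip path-length agreement


@dataclass(frozen=True)
class WGDLabel:
    """A WGD event placed on a gene-tree node: retained (present) or not."""

    event_index: int
    status: str  # PRESENT or MISSING

    def __post_init__(self):
        if self.status not in (PRESENT, MISSING):
            raise ValueError(f"invalid WGD label status {self.status!r}")


class TreeNode:
    """A node of a rooted binary tree.

    Every node has 0 or 2 children.  Child order is preserved from the input:
    the first-listed child is the left child, the second the right child.
    Attributes beyond the core topology are filled in lazily by the
    reconciliation / placement stages and default to inert values.
    """

    __slots__ = (
        "children",
        "parent",
        "length",
        "label",
        "species",
        "is_loss",
        "loss_species",
        "event",
        "wgd_labels",
        "mark",
        "age",
        "mapping",
        "species_set",
    )

    def __init__(self, label: str = "", length: Optional[float] = None):
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.length = length
        self.label = label
        self.species: Optional[str] = None  # species of a gene leaf
        self.is_loss = False
        self.loss_species: frozenset[str] = frozenset()
        self.event: Optional[str] = None  # 'speciation' | 'duplication'
        self.wgd_labels: list[WGDLabel] = []
        self.mark: Optional["WGDMark"] = None  # species-tree WGD mark
        self.age: Optional[float] = None  # MYA, for time-calibrated trees
        self.mapping: Optional[TreeNode] = None  # species-tree node (LCA map)
        self.species_set: Optional[frozenset[str]] = None

    # -- topology ---------------------------------------------------------

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def left(self) -> "TreeNode":
        return self.children[0]

    @property
    def right(self) -> "TreeNode":
        return self.children[1]

    def postorder(self) -> Iterator["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def descendants(self) -> Iterator["TreeNode"]:
        """All nodes strictly below this one."""
        for child in self.children:
            yield from child.preorder()

    def ancestors(self) -> Iterator["TreeNode"]:
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def validate_binary(self) -> None:
        for node in self.postorder():
            if len(node.children) not in (0, 2):
                raise TreeValidationError(
                    f"node {node.label!r} has {len(node.children)} children; "
                    "only binary trees are supported"
                )

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)}-children"
        return f"<TreeNode {self.label!r} {kind}>"


@dataclass(frozen=True)
class WGDMark:
    """A whole-genome duplication on a species-tree branch.

    The mark is identified by the child node of the branch it sits on, and by
    an absolute time in MYA strictly inside that branch's time interval.
    """

    event_index: int
    node: TreeNode = field(compare=False, hash=False)
    time: float


@dataclass(frozen=True)
class EventPair:
    """An ordered (older, younger) pair of WGD events on one root-to-tip
    trajectory of the species tree."""

    older_event: int
    younger_event: int


# ---------------------------------------------------------------------------
# Newick / NHX input


def _convert_dendropy(dnode, parent: Optional[TreeNode]) -> TreeNode:
    label = ""
    if dnode.taxon is not None and dnode.taxon.label is not None:
        label = dnode.taxon.label
    elif dnode.label is not None:
        label = dnode.label
    node = TreeNode(label=label, length=dnode.edge.length)
    if parent is not None:
        parent.add_child(node)
    for ann in dnode.annotations:
        _apply_nhx_key(node, ann.name, str(ann.value))
    for child in dnode.child_nodes():
        _convert_dendropy(child, node)
    return node


def _apply_nhx_key(node: TreeNode, key: str, value: str) -> None:
    if key == "W":
        node.mark = WGDMark(event_index=int(value), node=node,
                            time=node.mark.time if node.mark else float("nan"))
    elif key == "T":
        idx = node.mark.event_index if node.mark else -1
        node.mark = WGDMark(event_index=idx, node=node, time=float(value))
    elif key == "evt":
        node.wgd_labels = [WGDLabel(int(v), PRESENT) for v in value.split("+")]
    elif key == "st":
        statuses = [{"P": PRESENT, "M": MISSING}[v] for v in value.split("+")]
        node.wgd_labels = [
            WGDLabel(lab.event_index, s)
            for lab, s in zip(node.wgd_labels, statuses)
        ]
    elif key == "loss":
        node.is_loss = True
        node.loss_species = frozenset(value.split("+"))
    # unknown keys are ignored


def parse_newick(text: str, role: str = "gene") -> TreeNode:
    """Parse one Newick/NHX tree.

    Parameters
    ----------
    text:
        A single Newick tree, optionally with NHX comments.
    role:
        ``"species"`` validates time calibration (ultrametric within
        ``ULTRAMETRIC_TOL``), extracts WGD marks and checks that each mark's
        time lies strictly inside its branch's time interval.  ``"gene"``
        performs no time validation.

    Returns
    -------
    TreeNode
        The root of the converted tree.
    """
    if role not in ("gene", "species"):
        raise ValueError(f"unknown tree role {role!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    root = _convert_dendropy(dtree.seed_node, None)
    if role == "species":
        root.validate_binary()
        annotate_ages(root)
        _validate_marks(root)
    return root


def read_gene_trees(handle: Union[str, io.TextIOBase]) -> list[TreeNode]:
    """Read a gene-tree collection, one Newick tree per line."""
    if isinstance(handle, str):
        with open(handle, "r", encoding="utf-8") as fh:
            return read_gene_trees(fh)
    trees = []
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(parse_newick(line, role="gene"))
        except NewickParseError as exc:
            raise NewickParseError(f"line {lineno}: {exc}") from exc
    return trees


def annotate_ages(root: TreeNode) -> float:
    """Compute node ages (MYA) for an ultrametric tree; returns the root age.

    Requires branch lengths on every non-root edge and root-to-tip path
    lengths that agree within ``ULTRAMETRIC_TOL``.
    """
    depths: dict[int, float] = {id(root): 0.0}
    tip_depths = []
    for node in root.preorder():
        if node is root:
            continue
        if node.length is None:
            raise TreeValidationError(
                f"branch above {node.label!r} has no length; a time-calibrated "
                "tree needs branch lengths everywhere"
            )
        depths[id(node)] = depths[id(node.parent)] + node.length
        if node.is_leaf:
            tip_depths.append(depths[id(node)])
    if not tip_depths:
        root.age = 0.0
        return 0.0
    root_age = tip_depths[0]
    if max(tip_depths) - min(tip_depths) > ULTRAMETRIC_TOL:
        raise TreeValidationError(
            "tree is not ultrametric: root-to-tip path lengths range from "
            f"{min(tip_depths):g} to {max(tip_depths):g} MY"
        )
    for node in root.preorder():
        node.age = root_age - depths[id(node)]
    return root_age


def _validate_marks(root: TreeNode) -> None:
    seen: dict[int, TreeNode] = {}
    for node in root.preorder():
        mark = node.mark
        if mark is None:
            continue
        if mark.event_index < 0 or mark.time != mark.time:
            raise TreeValidationError(
                f"WGD mark on {node.label!r} needs both W=<index> and T=<time>"
            )
        if mark.event_index in seen:
            raise TreeValidationError(
                f"duplicate WGD event index {mark.event_index}"
            )
        seen[mark.event_index] = node
        if node.parent is None:
            raise TreeValidationError("a WGD mark cannot sit above the root")
        low, high = node.age, node.parent.age
        if not (low < mark.time < high):
            raise TreeValidationError(
                f"WGD event {mark.event_index}: time {mark.time:g} MYA is "
                f"outside its branch interval ({low:g}, {high:g})"
            )


# ---------------------------------------------------------------------------
# Newick / NHX output


def _fmt_length(x: float) -> str:
    return format(x, ".17g")


def _nhx_tags(node: TreeNode) -> str:
    tags = []
    if node.mark is not None:
        tags.append(f"W={node.mark.event_index}")
        tags.append(f"T={_fmt_length(node.mark.time)}")
    if node.wgd_labels:
        tags.append("evt=" + "+".join(str(l.event_index) for l in node.wgd_labels))
        tags.append("st=" + "+".join("P" if l.status == PRESENT else "M"
                                     for l in node.wgd_labels))
    if node.is_loss:
        tags.append("loss=" + "+".join(sorted(node.loss_species)))
    if not tags:
        return ""
    return "[&&NHX:" + ":".join(tags) + "]"


_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,'\"]")


def _fmt_label(label: str) -> str:
    if label and _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _write_node(node: TreeNode, out: list[str]) -> None:
    if node.children:
        out.append("(")
        for i, child in enumerate(node.children):
            if i:
                out.append(",")
            _write_node(child, out)
        out.append(")")
    out.append(_fmt_label(node.label))
    out.append(_nhx_tags(node))
    if node.length is not None:
        out.append(":" + _fmt_length(node.length))


def write_newick(root: TreeNode) -> str:
    """Serialize a tree to Newick/NHX (one line, semicolon-terminated)."""
    out: list[str] = []
    _write_node(root, out)
    out.append(";")
    return "".join(out)


# ---------------------------------------------------------------------------
# Species naming conventions

Convention = Union[str, Mapping[str, str], Callable[[str], str]]

_SUFFIX_RE = re.compile(r"^(.*?)(\d+)$")


def species_of_leaf(
    label: str,
    convention: Convention = "suffix",
    delimiter: str = "_",
    fld: int = -1,
) -> str:
    """Resolve a gene-leaf label to its species name.

    ``convention`` is one of:

    - ``"suffix"``: strip a trailing integer (``"a1"`` -> ``"a"``);
    - ``"delimiter"``: split on ``delimiter`` and take field ``fld``
      (``"Sp|gene"`` with delimiter ``"|"``, fld 0 -> ``"Sp"``);
    - an explicit leaf->species mapping;
    - any callable label -> species.
    """
    if callable(convention) and not isinstance(convention, Mapping):
        return convention(label)
    if isinstance(convention, Mapping):
        try:
            return convention[label]
        except KeyError:
            raise LeafMappingError(
                f"leaf {label!r} not present in the leaf->species map"
            ) from None
    if convention == "suffix":
        m = _SUFFIX_RE.match(label)
        if not m or not m.group(1):
            raise LeafMappingError(
                f"leaf {label!r} has no trailing integer to strip"
            )
        return m.group(1)
    if convention == "delimiter":
        parts = label.split(delimiter)
        if len(parts) < 2:
            raise LeafMappingError(
                f"leaf {label!r} does not contain delimiter {delimiter!r}"
            )
        try:
            return parts[fld]
        except IndexError:
            raise LeafMappingError(
                f"leaf {label!r}: no field {fld} after splitting on "
                f"{delimiter!r}"
            ) from None
    raise ValueError(f"unknown naming convention {convention!r}")


def assign_species(
    gene_root: TreeNode,
    convention: Convention = "suffix",
    delimiter: str = "_",
    fld: int = -1,
) -> None:
    """Set ``species`` on every non-loss leaf of a gene tree in place."""
    for leaf in gene_root.leaves():
        if leaf.is_loss:
            continue
        leaf.species = species_of_leaf(leaf.label, convention, delimiter, fld)


# ---------------------------------------------------------------------------
# Species-tree helpers


def clade_species(node: TreeNode) -> frozenset[str]:
    """Species names (leaf labels) of a species-tree clade."""
    return frozenset(leaf.label for leaf in node.leaves())


def collect_marks(species_root: TreeNode) -> list[WGDMark]:
    """All WGD marks on the species tree, oldest first."""
    marks = [n.mark for n in species_root.preorder() if n.mark is not None]
    return sorted(marks, key=lambda m: -m.time)


def _on_same_trajectory(older: WGDMark, younger: WGDMark) -> bool:
    """True when the younger mark's branch lies on a root-to-tip path through
    the older mark's branch (same branch allowed if the times are ordered)."""
    if younger.node is older.node:
        return younger.time < older.time
    return any(anc is older.node for anc in younger.node.ancestors())


def find_event_pairs(species_root: TreeNode) -> list[EventPair]:
    """All ordered (older, younger) WGD event pairs that share a phylogenetic
    trajectory from the root, sorted by (older age desc, younger age desc)."""
    marks = collect_marks(species_root)
    pairs = []
    for i, older in enumerate(marks):
        for younger in marks[i + 1:]:
            if _on_same_trajectory(older, younger):
                pairs.append(EventPair(older.event_index, younger.event_index))
    return pairs
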