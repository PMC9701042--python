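"""Birth-death gene-family simulation along a species tree with WGD events,
plus the balanced/caterpillar study fixtures and the placement-accuracy
harness.

Each gene lineage evolves independently down every species-tree branch in
continuous time: small-scale duplications (SSD) and losses arrive with
exponential waiting times at per-million-year rates, an SSD duplicates the
lineage, a loss terminates it, and at a marked WGD time every lineage alive
on that branch duplicates at once.  Lineages follow both species-tree
children at speciations.  Extinct subtrees are pruned (unary nodes
suppressed) so the observed tree contains only extant leaves, and the true
status of every WGD copy is recorded: *present* when both daughters of the
duplication left extant descendants, *missing* (anchored at the surviving
copy's position, the node a placement method would test) when only one did.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import TreeValidationError
from .reconcile import lca_reconcile, insert_loss_leaves, split_dup_root
from .retention import RetentionCounts
from .treecore import (
    MISSING,
    PRESENT,
    TreeNode,
    WGDMark,
    annotate_ages,
)
from .wgd_place import PlacementResult, place_all

__all__ = [
    "SimulationConfig",
    "SimulatedTree",
    "AccuracyRecord",
    "simulate_gene_tree",
    "make_balanced",
    "make_caterpillar",
    "accuracy",
    "evaluate_placement",
    "run_grid",
    "simulate_independent_retention_counts",
    "PAPER_RATE_GRID",
]

#: the SSD/loss rate grid used throughout the accuracy study (events per MY)
PAPER_RATE_GRID = (0.01, 0.009, 0.002, 0.0002, 0.00002)

#: default branch length between consecutive speciations in the fixtures (MY)
FIXTURE_EDGE_MY = 30.0


@dataclass(frozen=True)
class SimulationConfig:
    """Rates are events per lineage per million years."""

    ssd_rate: float = 0.0
    loss_rate: float = 0.0
    n_trees: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.ssd_rate) and np.isfinite(self.loss_rate)):
            raise ValueError("rates must be finite")
        if self.ssd_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")


@dataclass
class SimulatedTree:
    """One simulated gene family.

    ``root`` is ``None`` when every lineage went extinct.  ``truth`` holds
    (event_index, node, status) triples referring to nodes of the observed
    (pruned) tree.
    """

    root: Optional[TreeNode]
    truth: list[tuple[int, TreeNode, str]] = field(default_factory=list)
    n_ssd: int = 0
    n_loss: int = 0
    ssd_by_branch: dict[str, int] = field(default_factory=dict)

    @property
    def extinct(self) -> bool:
        return self.root is None


@dataclass(frozen=True)
class AccuracyRecord:
    tree_type: str
    spacing: int
    ssd_rate: float
    loss_rate: float
    accuracy: float
    n_trees: int
    correct: int = 0
    called: int = 0
    n_extinct: int = 0


# ---------------------------------------------------------------------------
# Core simulation


class _Sim:
    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.total_rate = config.ssd_rate + config.loss_rate
        self.truth: list[tuple[int, TreeNode, str]] = []
        self.n_ssd = 0
        self.n_loss = 0
        self.ssd_by_branch: dict[str, int] = {}

    def _branch_key(self, sp: TreeNode) -> str:
        return sp.label or "clade:" + "+".join(
            sorted(leaf.label for leaf in sp.leaves())
        )

    def evolve(self, sp: TreeNode, t: float, wgd_ahead: bool) -> Optional[TreeNode]:
        """One gene lineage on the branch above ``sp`` from age ``t`` down.

        Returns the root of the surviving subtree, or ``None`` on extinction.
        """
        mark = sp.mark if (wgd_ahead and sp.mark is not None) else None
        mark_time = mark.time if mark is not None and mark.time < t else -np.inf
        t_event = (
            t - self.rng.exponential(1.0 / self.total_rate)
            if self.total_rate > 0
            else -np.inf
        )
        if t_event > max(mark_time, sp.age):
            # a stochastic event strikes first (ages decrease toward present)
            if self.rng.random() < self.cfg.ssd_rate / self.total_rate:
                self.n_ssd += 1
                key = self._branch_key(sp)
                self.ssd_by_branch[key] = self.ssd_by_branch.get(key, 0) + 1
                node = TreeNode()
                node.age = t_event
                return self._join(
                    node,
                    self.evolve(sp, t_event, wgd_ahead),
                    self.evolve(sp, t_event, wgd_ahead),
                )
            self.n_loss += 1
            return None
        if mark_time > sp.age:
            node = TreeNode()
            node.age = mark_time
            a = self.evolve(sp, mark_time, False)
            b = self.evolve(sp, mark_time, False)
            joined = self._join(node, a, b)
            if a is not None and b is not None:
                self.truth.append((mark.event_index, node, PRESENT))
            elif joined is not None:
                self.truth.append((mark.event_index, joined, MISSING))
            return joined
        # bottom of the branch
        if sp.is_leaf:
            leaf = TreeNode(label=sp.label)
            leaf.species = sp.label
            leaf.age = sp.age
            return leaf
        node = TreeNode()
        node.age = sp.age
        return self._join(
            node,
            self.evolve(sp.children[0], sp.age, True),
            self.evolve(sp.children[1], sp.age, True),
        )

    @staticmethod
    def _join(
        node: TreeNode, a: Optional[TreeNode], b: Optional[TreeNode]
    ) -> Optional[TreeNode]:
        """Attach surviving children, suppressing the node when fewer than
        two survive."""
        survivors = [c for c in (a, b) if c is not None]
        if not survivors:
            return None
        if len(survivors) == 1:
            return survivors[0]
        for child in survivors:
            node.add_child(child)
        return node


def simulate_gene_tree(
    species_root: TreeNode,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedTree:
    """Simulate one gene family along a time-calibrated species tree.

    The species tree must carry ages (see :func:`treecore.annotate_ages`);
    WGD marks, if any, trigger a simultaneous duplication of every live
    lineage on their branch.
    """
    if species_root.age is None:
        annotate_ages(species_root)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sim = _Sim(config, rng)
    if species_root.is_leaf:
        root = sim.evolve(species_root, species_root.age, True)
    else:
        node = TreeNode()
        node.age = species_root.age
        root = _Sim._join(
            node,
            sim.evolve(species_root.children[0], species_root.age, True),
            sim.evolve(species_root.children[1], species_root.age, True),
        )
    if root is not None:
        _finalize(root)
    return SimulatedTree(
        root=root,
        truth=sim.truth,
        n_ssd=sim.n_ssd,
        n_loss=sim.n_loss,
        ssd_by_branch=sim.ssd_by_branch,
    )


def _finalize(root: TreeNode) -> None:
    """Set branch lengths from ages and number the leaves per species."""
    counters: dict[str, int] = {}
    for node in root.preorder():
        node.length = None if node.parent is None else node.parent.age - node.age
        if node.is_leaf:
            sp = node.species
            counters[sp] = counters.get(sp, 0) + 1
            node.label = f"{sp}{counters[sp]}"


# ---------------------------------------------------------------------------
# Study fixtures


def _species_names(n: int):
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for size in itertools.count(1):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)
            n -= 1
            if n == 0:
                return


def _mark(node: TreeNode, event_index: int) -> None:
    node.mark = WGDMark(
        event_index=event_index,
        node=node,
        time=(node.age + node.parent.age) / 2.0,
    )


def make_balanced(spacing: int, edge: float = FIXTURE_EDGE_MY) -> TreeNode:
    """A balanced (maximally symmetric) species tree with two nested WGD
    events ``spacing`` speciation events apart on the leftmost trajectory.

    The tree has ``2**(spacing + 1)`` leaves and uniform ``edge``-MY
    branches; the older event sits mid-branch above the first internal node
    under the root, the younger mid-branch above the leftmost leaf.
    """
    if spacing < 1:
        raise TreeValidationError("event spacing must be at least 1")
    depth = spacing + 1

    def build(level: int) -> TreeNode:
        node = TreeNode(length=edge if level else None)
        if level < depth:
            node.add_child(build(level + 1))
            node.add_child(build(level + 1))
        return node

    root = build(0)
    names = _species_names(2 ** depth)
    for leaf in root.leaves():
        leaf.label = next(names)
    annotate_ages(root)
    node = root.children[0]
    _mark(node, 0)
    for _ in range(spacing):
        node = node.children[0]
    _mark(node, 1)
    return root


def make_caterpillar(spacing: int, edge: float = FIXTURE_EDGE_MY) -> TreeNode:
    """A caterpillar (fully pectinate) species tree with two nested WGD
    events ``spacing`` speciation events apart along the ladder.

    The ladder has ``spacing + 2`` internal nodes and ``spacing + 3`` leaves,
    with ``edge``-MY rungs; the older event sits mid-branch above the first
    ladder node under the root, the younger mid-branch above the last.
    """
    if spacing < 1:
        raise TreeValidationError("event spacing must be at least 1")
    n_internal = spacing + 2
    names = _species_names(n_internal + 1)
    root = TreeNode()
    chain = [root]
    for k in range(1, n_internal):
        inner = TreeNode(length=edge)
        outer = TreeNode(label=next(names), length=edge * (n_internal - k + 1))
        chain[-1].add_child(inner)
        chain[-1].add_child(outer)
        chain.append(inner)
    for _ in range(2):
        chain[-1].add_child(TreeNode(label=next(names), length=edge))
    annotate_ages(root)
    _mark(chain[1], 0)
    _mark(chain[-1], 1)
    return root


# ---------------------------------------------------------------------------
# Accuracy harness


def evaluate_placement(
    sim: SimulatedTree, species_root: TreeNode
) -> list[PlacementResult]:
    """Run the full inference pipeline on one simulated observed tree.

    The simulated rooting is kept (the simulator emits rooted trees);
    duplication-rooted trees are split, losses are inserted, and every marked
    event is placed.  The observed tree is annotated in place, so truth
    labels keep referring to the same node objects.
    """
    if sim.extinct:
        return []
    recon = lca_reconcile(sim.root, species_root)
    parts = split_dup_root(recon, species_root)
    placements = []
    for part in parts:
        insert_loss_leaves(part)
        placements.append(place_all(part.root, species_root))
    return placements


def accuracy(
    placements: PlacementResult | Sequence[PlacementResult],
    truth: SimulatedTree,
) -> tuple[int, int]:
    """(correct, called) for inferred WGD labels against simulation truth.

    A label is correct when event index, node identity and present/missing
    status all match.  ``called`` is the number of inferred labels; a tree
    with no inferred labels contributes (0, 0).
    """
    if isinstance(placements, PlacementResult):
        placements = [placements]
    inferred = [
        (evt, id(node), status)
        for p in placements
        for evt, node, status in p.all_labels()
    ]
    truth_set = {(evt, id(node), status) for evt, node, status in truth.truth}
    correct = sum(1 for lab in inferred if lab in truth_set)
    return correct, len(inferred)


def run_grid(
    tree_fixtures: Sequence[tuple[str, int, TreeNode]],
    rate_grid: Sequence[tuple[float, float]],
    n_trees: int,
    seed: int = 0,
) -> list[AccuracyRecord]:
    """Placement accuracy for every (fixture, ssd_rate, loss_rate) condition.

    ``tree_fixtures`` holds (tree_type, spacing, species_root) triples;
    ``rate_grid`` holds (ssd_rate, loss_rate) pairs.  Per condition,
    ``n_trees`` families are simulated, the inference pipeline is run on each
    observed tree, and correct/called tallies are pooled.  Fully extinct
    families are excluded from the denominator and reported separately.
    Deterministic given ``seed``.
    """
    records = []
    for fi, (tree_type, spacing, species_root) in enumerate(tree_fixtures):
        for ri, (ssd_rate, loss_rate) in enumerate(rate_grid):
            rng = np.random.default_rng([seed, fi, ri])
            cfg = SimulationConfig(
                ssd_rate=ssd_rate, loss_rate=loss_rate,
                n_trees=n_trees, seed=seed,
            )
            correct = called = n_extinct = 0
            for _ in range(n_trees):
                sim = simulate_gene_tree(species_root, cfg, rng)
                if sim.extinct:
                    n_extinct += 1
                    continue
                placements = evaluate_placement(sim, species_root)
                c, k = accuracy(placements, sim)
                correct += c
                called += k
            records.append(
                AccuracyRecord(
                    tree_type=tree_type,
                    spacing=spacing,
                    ssd_rate=ssd_rate,
                    loss_rate=loss_rate,
                    accuracy=correct / called if called else float("nan"),
                    n_trees=n_trees,
                    correct=correct,
                    called=called,
                    n_extinct=n_extinct,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Calibration data for the retention statistic


def simulate_independent_retention_counts(
    n_trees: int,
    rng: np.random.Generator,
    p_older_present: float = 0.5,
    p_younger_retained: float = 0.5,
    n_younger: int = 2,
) -> list[RetentionCounts]:
    """Per-tree retention tallies with the younger event's retention drawn
    independently of the older event's status (true ratio exactly 1).

    Each tree carries one older-event node (present with probability
    ``p_older_present``) and ``n_younger`` younger-event nodes, each retained
    independently with probability ``p_younger_retained``.  Used to calibrate
    bootstrap interval coverage of the retention ratio.
    """
    out = []
    for _ in range(n_trees):
        copies = int(rng.binomial(n_younger, p_younger_retained))
        if rng.random() < p_older_present:
            out.append(RetentionCounts(copies, n_younger, 0, 0))
        else:
            out.append(RetentionCounts(0, 0, copies, n_younger))
    return out
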