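"""Conditional duplicate-retention counting and the retention probability
ratio for a consecutive pair of WGD events.

For a pair of nested WGD events (older, younger) on one species-tree
trajectory, every gene-tree node labeled with the older event opens a tally:
each younger-event label among its descendants is one *possible* duplicate
copy, and each younger-event label with status "present" is one *retained*
copy.  Tallies accrue to the RR class when the older duplicate was retained
(present) and to the LR class when it was lost (missing).  The test statistic
is the ratio of the two conditional retention rates,

    Pratio = P(retained after younger | retained after older)
           / P(retained after younger | not retained after older)
           = (rr_copies / rr_possible) / (lr_copies / lr_possible),

which equals 1 when retention in the second event is independent of the
outcome of the first.  Uncertainty comes from a nonparametric bootstrap over
gene trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import BootstrapFailureError, UndefinedStatisticError
from .treecore import MISSING, PRESENT, EventPair
from .wgd_place import PlacementResult

__all__ = [
    "RetentionCounts",
    "PratioResult",
    "BootstrapResult",
    "count_retention",
    "aggregate_counts",
    "pratio",
    "bootstrap_pratio",
]


@dataclass(frozen=True)
class RetentionCounts:
    """Retained/possible duplicate-copy tallies for one event pair."""

    rr_copies: int = 0
    rr_possible: int = 0
    lr_copies: int = 0
    lr_possible: int = 0

    def __post_init__(self):
        if self.rr_copies > self.rr_possible or self.lr_copies > self.lr_possible:
            raise ValueError("copies cannot exceed possible copies")
        if min(self.rr_copies, self.rr_possible,
               self.lr_copies, self.lr_possible) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "RetentionCounts") -> "RetentionCounts":
        return RetentionCounts(
            self.rr_copies + other.rr_copies,
            self.rr_possible + other.rr_possible,
            self.lr_copies + other.lr_copies,
            self.lr_possible + other.lr_possible,
        )

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.rr_copies, self.rr_possible,
                self.lr_copies, self.lr_possible)


@dataclass(frozen=True)
class PratioResult:
    pratio: float
    rr_rate: float
    lr_rate: float
    counts: RetentionCounts
    n_trees_contributing: int = 0


@dataclass(frozen=True)
class BootstrapResult:
    point_estimate: float
    interval_low: float
    interval_high: float
    p_value: float
    n_replicates: int
    seed: int
    n_redrawn: int = 0  # replicates redrawn because the statistic was undefined


def _has_extant_leaf(node) -> bool:
    return any(not leaf.is_loss for leaf in node.leaves())


def count_retention(placed: PlacementResult, pair: EventPair) -> RetentionCounts:
    """Tally retained vs possible younger-event duplicates under every node
    labeled with the older event of ``pair``.

    A present younger-event label contributes one retained copy; its node is
    defensively checked to keep at least one extant (non-loss) leaf in each
    child subtree, which reconstructed duplication nodes always do.  Returns
    all-zero counts when either event is absent from the tree.
    """
    older = placed.labeled_nodes(pair.older_event)
    younger = {
        id(node): (node, status)
        for node, status in placed.labeled_nodes(pair.younger_event)
    }
    rr_c = rr_p = lr_c = lr_p = 0
    for older_node, older_status in older:
        copies = 0
        possible = 0
        for desc in older_node.descendants():
            hit = younger.get(id(desc))
            if hit is None:
                continue
            node, status = hit
            possible += 1
            if status == PRESENT:
                if not all(_has_extant_leaf(c) for c in node.children):
                    raise AssertionError(
                        "present WGD label on a node without extant leaves "
                        "in both subtrees"
                    )
                copies += 1
        if older_status == PRESENT:
            rr_c += copies
            rr_p += possible
        else:
            lr_c += copies
            lr_p += possible
    return RetentionCounts(rr_c, rr_p, lr_c, lr_p)


def aggregate_counts(per_tree: Iterable[RetentionCounts]) -> RetentionCounts:
    """Elementwise sum of per-tree tallies."""
    total = RetentionCounts()
    for counts in per_tree:
        total = total + counts
    return total


def pratio(counts: RetentionCounts, n_trees_contributing: int = 0) -> PratioResult:
    """The retention probability ratio from aggregated tallies.

    Raises :class:`UndefinedStatisticError` when a conditional rate has an
    empty denominator (``no_rr_data`` / ``no_lr_data``) or the LR rate is
    zero (``zero_lr_rate``), each with a distinct error code.
    """
    if counts.rr_possible == 0:
        raise UndefinedStatisticError(
            "no_rr_data", "no possible duplicate copies in the RR class"
        )
    if counts.lr_possible == 0:
        raise UndefinedStatisticError(
            "no_lr_data", "no possible duplicate copies in the LR class"
        )
    rr_rate = counts.rr_copies / counts.rr_possible
    lr_rate = counts.lr_copies / counts.lr_possible
    if lr_rate == 0.0:
        raise UndefinedStatisticError(
            "zero_lr_rate", "LR retention rate is zero; the ratio diverges"
        )
    return PratioResult(
        pratio=rr_rate / lr_rate,
        rr_rate=rr_rate,
        lr_rate=lr_rate,
        counts=counts,
        n_trees_contributing=n_trees_contributing,
    )


def bootstrap_pratio(
    per_tree: Sequence[RetentionCounts],
    n_replicates: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the aggregate retention ratio over gene trees.

    Trees are resampled with replacement ``n_replicates`` times and the
    aggregate ratio recomputed per replicate.  Replicates on which the
    statistic is undefined are redrawn (their number is reported); if valid
    replicates cannot be collected within twice the requested number of
    draws — i.e. the statistic is undefined in more than half of them — the
    bootstrap fails with a diagnostic.  The interval is the 2.5/97.5
    percentile band and the p-value is the two-sided bootstrap tail
    probability against the independence value 1, floored at
    ``1 / n_replicates``.
    """
    if len(per_tree) < 2:
        raise ValueError("bootstrap needs per-tree counts from at least 2 trees")
    point = pratio(aggregate_counts(per_tree), len(per_tree)).pratio
    rng = np.random.default_rng(seed)
    data = np.array([c.as_tuple() for c in per_tree], dtype=np.int64)
    n = len(per_tree)
    values: list[float] = []
    n_undefined = 0
    max_draws = 2 * n_replicates
    draws = 0
    while len(values) < n_replicates and draws < max_draws:
        draws += 1
        idx = rng.integers(0, n, size=n)
        rr_c, rr_p, lr_c, lr_p = data[idx].sum(axis=0)
        if rr_p == 0 or lr_p == 0 or lr_c == 0:
            n_undefined += 1
            continue
        values.append((rr_c / rr_p) / (lr_c / lr_p))
    if len(values) < n_replicates:
        raise BootstrapFailureError(
            f"retention ratio undefined in {n_undefined} of {draws} bootstrap "
            "draws (more than half); the data cannot support the bootstrap",
            n_valid=len(values),
            n_undefined=n_undefined,
        )
    arr = np.array(values)
    low, high = np.percentile(arr, [2.5, 97.5])
    frac_le = float(np.mean(arr <= 1.0))
    frac_ge = float(np.mean(arr >= 1.0))
    p_value = min(1.0, 2.0 * min(frac_le, frac_ge))
    p_value = max(p_value, 1.0 / n_replicates)
    return BootstrapResult(
        point_estimate=point,
        interval_low=float(low),
        interval_high=float(high),
        p_value=p_value,
        n_replicates=n_replicates,
        seed=seed,
        n_redrawn=n_undefined,
    )
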