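"""Gene-family construction utilities: homolog-pair filtering and
single-linkage clustering.

These mirror the filters applied between an all-against-all protein search
and tree building: keep homolog pairs whose percent identity and percent
ungapped both clear a threshold (60% by default), then form families as the
connected components of the surviving pair graph.  Running the search,
aligner and tree builders themselves is out of scope; this module only
consumes their tabular output.

"Percent ungapped" is defined here as ``100 * (alignment_length - gaps) /
alignment_length`` and is computed from the tabular columns when not given
directly; tabular dialects differ, so the column mapping is configurable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .errors import WGDKitError

__all__ = [
    "HomologPair",
    "read_pairs",
    "filter_pairs",
    "single_linkage",
    "family_sizes",
    "small_families",
]

#: default column layout of 12-column tabular search output
OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class HomologPair:
    query_id: str
    subject_id: str
    percent_identity: float
    percent_ungapped: float
    e_value: float = 0.0

    def __post_init__(self):
        if not self.query_id or not self.subject_id:
            raise ValueError("pair ids must be non-empty")
        for pct in (self.percent_identity, self.percent_ungapped):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"percentage {pct} outside [0, 100]")
        if self.e_value < 0:
            raise ValueError("e-value must be non-negative")


def read_pairs(
    source: Union[str, io.TextIOBase],
    columns: Optional[Sequence[str]] = None,
    gap_column: str = "gapopen",
) -> list[HomologPair]:
    """Read homolog pairs from tabular (outfmt-6-style) TSV.

    ``columns`` overrides the column layout; it must include ``qseqid``,
    ``sseqid`` and ``pident``.  Percent ungapped is taken from a
    ``pungapped`` column when present, otherwise computed as
    ``100 * (length - <gap_column>) / length``.
    """
    cols = list(columns) if columns is not None else list(OUTFMT6_COLUMNS)
    try:
        df = pd.read_csv(source, sep="\t", header=None, names=cols,
                         comment="#", dtype=str)
    except Exception as exc:
        raise WGDKitError(f"cannot read homolog-pair table: {exc}") from exc
    for required in ("qseqid", "sseqid", "pident"):
        if required not in cols:
            raise WGDKitError(f"column layout lacks {required!r}")
    pairs = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(cols, row))
        try:
            pident = float(rec["pident"])
            if "pungapped" in rec:
                pungapped = float(rec["pungapped"])
            else:
                length = float(rec["length"])
                pungapped = 100.0 * (length - float(rec[gap_column])) / length
            evalue = float(rec.get("evalue", 0.0) or 0.0)
            pairs.append(
                HomologPair(rec["qseqid"], rec["sseqid"],
                            pident, pungapped, evalue)
            )
        except (KeyError, TypeError, ValueError, ZeroDivisionError) as exc:
            raise WGDKitError(f"line {i}: unparseable pair row: {exc}") from exc
    return pairs


def filter_pairs(
    pairs: Iterable[HomologPair],
    min_identity: float = 60.0,
    min_ungapped: float = 60.0,
) -> list[HomologPair]:
    """Keep pairs with percent identity AND percent ungapped at or above the
    thresholds (order-preserving; the 60/60 defaults match common practice
    for intra-clade proteome comparisons)."""
    return [
        p
        for p in pairs
        if p.percent_identity >= min_identity
        and p.percent_ungapped >= min_ungapped
    ]


def single_linkage(pairs: Iterable[HomologPair]) -> list[frozenset[str]]:
    """Gene families as connected components of the homolog-pair graph,
    sorted by their smallest member id."""
    graph = nx.Graph()
    for p in pairs:
        graph.add_node(p.query_id)
        graph.add_node(p.subject_id)
        graph.add_edge(p.query_id, p.subject_id)
    families = [frozenset(c) for c in nx.connected_components(graph)]
    return sorted(families, key=lambda fam: min(fam))


def family_sizes(families: Sequence[frozenset[str]]) -> Mapping[int, int]:
    """Histogram of family sizes."""
    hist: dict[int, int] = {}
    for fam in families:
        hist[len(fam)] = hist.get(len(fam), 0) + 1
    return dict(sorted(hist.items()))


def small_families(
    families: Sequence[frozenset[str]], min_size: int = 4
) -> list[frozenset[str]]:
    """Families below the tree-building size threshold (flagged, not
    deleted: trees are only built for families of ``min_size`` or more)."""
    return [fam for fam in families if len(fam) < min_size]
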