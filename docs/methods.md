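# Methods

## Scope and model

The toolkit answers one question: after two consecutive whole-genome
duplications (WGDs) on a lineage, is a gene's retention in the second event
contingent on its retention in the first? The unit of observation is a gene
family (one gene tree); the statistic pools retained/possible duplicate
counts over families.

All trees are rooted and strictly binary. The species tree is
time-calibrated (branch lengths in MY; ultrametricity validated to 1e-6 MY,
since WGD times in MYA are only meaningful on a clock tree). A WGD is a
point on a species-tree branch, encoded as an NHX comment
`[&&NHX:W=<index>:T=<MYA>]` on the branch's child node; `T` must lie
strictly inside the branch's time interval, and event indices are unique.
The NHX schema is this package's own (the format only standardizes the
comment envelope). Child order is preserved from input; "left"/"right"
mean first/second listed. One mark per branch is supported; pairs of events
are ancestor–descendant marks on a shared root-to-tip trajectory.

## Reconciliation

Standard LCA-mapping parsimony reconciliation: each gene node maps to the
species-tree LCA of its leaves' species; a node is a duplication exactly
when it maps to the same species node as one of its children; losses are
counted along the species-tree path each child mapping skips (one fewer for
speciation nodes, whose mapping itself consumes one step). Unrooted input
trees are rooted by scoring **every** edge's rooting and keeping the
minimal duplications+losses; ties break to the lowest edge index in a fixed
post-order enumeration, making results deterministic. Trees whose root is a
duplication spanning more than one species are split iteratively into their
root subtrees (each re-labeled) until every root is a speciation: a root
duplication predates the species root and therefore predates every marked
WGD, so discarding the root node loses no placement signal. Single-species
trees pass through unchanged; they can still receive terminal-branch WGD
labels but contribute no speciation-rooted structure.

Inferred losses are materialized as explicit *loss leaves* carrying the
species set of the pruned clade. After insertion, every internal node's
observed+lost species set equals the full species set of its mapping's
clade (a property-tested invariant). Loss leaves support the placement
candidacy test below but are never themselves labeled and never counted as
retained copies.

## Event placement

For an event on the branch above species node `s`, the candidate gene nodes
are the most recent nodes whose (observed+lost) species set equals the
species set of `s`'s clade. They are found by descending to the LCA of all
leaves carrying clade species; if that node's species set strictly contains
the clade, the node is a duplication predating the WGD and the search
recurses into both children (the event may exist in both copies). If the
subtree samples only part of the clade with nothing marking the remainder
as lost, the family does not span the event on that lineage and contributes
nothing (missing-by-loss cannot be distinguished from missing-by-sampling
there; occurrences are logged).

Each candidate is labeled by a parsimony rule: a non-duplication candidate
is a **missing** event (the duplicate was lost); a duplication candidate is
**present** — unless both its children are also duplications, in which case
the candidate itself is interpreted as an SSD that predates the WGD and the
event descends onto both children. This one-level children check minimizes
the number of duplications attributed to SSD; remaining unexplained
duplications are reported as SSDs. When equally parsimonious placements
exist the rootward (older) node wins, which falls out of the LCA descent
naturally. Events are placed independently, oldest first; the counting
stage imposes the ancestor–descendant relation between paired events.

## Retention counting and the ratio

For an (older, younger) event pair: under every node labeled with the older
event, each descendant node labeled with the younger event (present *or*
missing) is one possible duplicate copy, and each present one is one
retained copy (defensively verified to keep extant leaves in both child
subtrees). Tallies accrue to the RR class when the older label is present
and to the LR class when it is missing. Per-tree tallies are summed over
families and

    Pratio = (rr_copies / rr_possible) / (lr_copies / lr_possible).

Degenerate aggregates raise typed errors rather than returning sentinel
numbers: empty RR or LR denominators and a zero LR rate each carry a
distinct error code, so a caller (and the CLI, via exit code 3) can
distinguish "no data" from "division by zero". Counting missing
younger-event nodes toward "possible" is forced by the worked example (one
retained and one unretained side give possible = 2).

Uncertainty: nonparametric bootstrap over gene trees (default 1000
replicates, matching common practice for this statistic), percentile 95%
interval, and a two-sided empirical p-value against Pratio = 1 floored at
1/replicates — the resolution limit of a finite bootstrap. Replicates with
an undefined statistic are redrawn and counted; if more than half of draws
are undefined the bootstrap aborts with diagnostics. All resampling flows
from one integer seed through `numpy.random.default_rng`; identical seeds
give bit-identical results. Event pairs are analyzed independently with no
multiple-testing correction. All gene trees passing the species filter stay
in the resampling universe, zero-count trees included (they cannot change
the point estimate but do widen intervals honestly).

## Simulator

Gene families evolve per lineage in continuous time down each species
branch: SSD and loss arrivals are exponential waiting times at configured
per-MY rates (equivalent to Poisson arrival counts per branch — a tested
law); an SSD duplicates the lineage, a loss terminates it, and at a marked
time `T` every lineage alive on that branch duplicates simultaneously.
Whether an SSD on a marked branch falls before or after the WGD is decided
by its arrival time relative to `T`. Extinct subtrees are pruned and unary
nodes suppressed; branch lengths derive from event ages, so suppression is
exact. Fully extinct families return a sentinel and are excluded from
accuracy denominators (reported separately).

Ground truth per WGD copy: **present** anchored at the duplication node
when both daughters leave extant descendants; **missing** anchored at the
surviving daughter's pruned position — the node a placement method would
test — when one daughter dies out; no record when both die. This anchoring
convention is a design choice that makes node-level accuracy comparison
well defined.

Accuracy experiments use two fixture shapes with two nested events
`spacing` speciations apart: a **balanced** tree of depth `spacing + 1`
(uniform 30 MY branches, `2^(spacing+1)` leaves; older event below the
root, younger on the leftmost terminal branch) and a **caterpillar** ladder
with `spacing + 2` internal nodes and 30 MY rungs. The 30 MY scale mirrors
tens-of-MY divergences typical of plant WGD studies; it is configurable,
since only event-count expectations (rate × length) depend on it. The rate
grid {0.01, 0.009, 0.002, 0.0002, 0.00002} events/MY spans published
duplication/loss rate estimates. An inferred label is correct iff event
index, node identity and status all match truth; accuracy = correct /
called, pooled over trees per condition. Inference on simulated trees keeps
the simulator's rooting (the trees are emitted rooted), then applies the
same splitting/loss-insertion/placement pipeline as real data.

Problem sizes: tests and the grid harness use 100 trees per condition and
1000 replicates for distributional laws — enough for the bootstrap
intervals that back the trend checks to separate the compared conditions,
while keeping the whole suite fast. Bootstrap-coverage calibration uses a
direct counts generator (`simulate_independent_retention_counts`) in which
the younger event's retention is independent of the older event's status by
construction (true ratio exactly 1): one older node and two younger slots
per family, statuses Bernoulli(0.5) — the cleanest null for interval
coverage, deliberately free of placement error.

What the simulator does **not** emulate: gene-tree estimation error
(topologies are true by construction), sequence evolution and alignment
noise, rate variation across branches or families, synteny, and
hybridization. Passing tests therefore validate the placement and counting
machinery, not robustness to phylogenetic reconstruction error in real
proteome data.

## Family utilities

Homolog-pair filtering keeps pairs with percent identity ≥ 60 **and**
percent ungapped ≥ 60 (both inclusive, both configurable); "percent
ungapped" is defined here as `100 × (alignment length − gaps) / alignment
length`, computed from tabular columns when not given directly — tabular
dialects differ, so the column layout is configurable. Families are
connected components (single linkage) of the filtered pair graph, ordered
by smallest member id; families under 4 members are flagged (trees are
usually built only at size ≥ 4) but never deleted. Running the homology
search, aligner, or tree builders is out of scope.

## Known limitations

* Multifurcating gene trees are rejected rather than resolved.
* One WGD mark per species-tree branch; same-branch event pairs are not
  meaningfully placeable by the species-set candidacy test.
* The earlier-node tie-break could in principle bias placements in
  pathological topologies; no correction is applied.
* The ratio is undefined when either retention class has no data; with few
  families the bootstrap may abort for the same reason. This is by design —
  a sentinel value would silently poison aggregates.
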