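# wgdkit

Toolkit for studying duplicate-gene retention after **whole-genome
duplications (WGDs)**. Given a time-calibrated species tree on which WGD
events are marked and a collection of gene trees, it

1. roots each gene tree by minimizing duplications + losses against the
   species tree, labels duplication/speciation nodes by LCA reconciliation,
   and splits duplication-rooted trees;
2. maps every marked WGD event onto each gene tree, labeling the event
   **present** (the duplicate survived in this family) or **missing** (it
   was lost) while separating small-scale duplications (SSDs) from WGD
   duplicates;
3. for a pair of consecutive WGD events on one lineage, computes the
   conditional retention probability ratio

   ```
   Pratio = P(retained after WGD #2 | retained after WGD #1)
          / P(retained after WGD #2 | not retained after WGD #1)
   ```

   with bootstrap confidence intervals and p-values against the
   independence value 1;
4. simulates gene families along the species tree under a continuous-time
   birth–death process with WGDs (ground truth recorded), to measure the
   placement method's accuracy.

`Pratio > 1` is the naive expectation under the gene-duplicability
hypothesis (genes retained once are retained again); `Pratio ≈ 1` indicates
independence of retention between consecutive events. The intended users
are comparative genomicists with polyploid lineages in their species tree —
e.g. the orchid *Phalaenopsis equestris*, whose lineage carries consecutive
WGDs at roughly 130 and 76 MYA, for which this type of analysis on
thousands of gene trees yields a Pratio slightly *below* 1 (reported as
0.94, 95% CI 0.93–0.96). Reproducing that number requires seven proteomes
plus an external homology-search/alignment/tree-building pipeline, so it is
context here, not a test target; everything in this repository runs on
programmatically generated trees.

## Input conventions

* Species tree: Newick with branch lengths in millions of years
  (ultrametric). A WGD on a branch is an NHX comment on the branch's child
  node: `[&&NHX:W=<event index>:T=<time MYA>]`, `T` strictly inside the
  branch's time interval.
* Gene trees: one Newick tree per line; unrooted input is fine. Leaf labels
  encode the species via a configurable convention: trailing integer
  (`a1 → a`), delimiter field, or an explicit two-column TSV map.

## Worked example

The canonical single-family scenario: an older WGD (event 0) whose
duplicate pair A1/A2 both survive, then a younger WGD (event 1) after which
A1's duplicate pair is retained and A2's duplicate is lost.

```python
import wgdkit as w

species = w.parse_newick(
    "((a[&&NHX:W=1:T=15]:30,b:30)[&&NHX:W=0:T=45]:30,(c:30,d:30):30);",
    role="species")
gene = w.parse_newick("((((a1,a2),b1),(a3,b2)),(c1,d1));")
w.assign_species(gene, "suffix")

placed, = w.place_unrooted(gene, species)
print(placed.all_labels())
counts = w.count_retention(placed, w.EventPair(0, 1))
print(counts.as_tuple())
```

prints (node reprs abbreviated):

```
[(0, <TreeNode ...>, 'present'), (1, <TreeNode ...>, 'present'), (1, <TreeNode 'a3' leaf>, 'missing')]
(1, 2, 0, 0)
```

Event 0 is present (the family kept both older copies); beneath it event 1
was possible twice and retained once, so the RR-class conditional retention
probability is `1/2 = 0.5`. There is no LR data in this single family
(the older duplicate was retained), so the ratio itself is undefined —
`wgdkit.pratio` raises `UndefinedStatisticError(code="no_lr_data")` —
exactly the degenerate case the aggregate over many families resolves.

The same analysis from the shell:

```sh
wgdkit place    --species-tree sp.nwk --gene-trees genes.nwk --out out/
wgdkit pratio   --species-tree sp.nwk --gene-trees genes.nwk \
                --pair 0:1 --replicates 1000 --seed 1 --out out/
wgdkit simulate --fixture balanced --spacing 1 --ssd-rate 0.002 \
                --loss-rate 0.002 --n-trees 100 --seed 1 --out sim/
wgdkit evaluate --fixture caterpillar --spacing 1 --spacing 3 \
                --n-trees 100 --seed 1 --out eval/
wgdkit families --pairs blast.tsv --out fam/
```

`pratio` writes `pratio.json` with the ratio, both conditional rates, the
aggregated counts, the bootstrap 95% interval and p-value; `evaluate`
writes a TSV of placement accuracy per (tree shape, spacing, SSD rate,
loss rate) condition. Exit codes: 0 success, 2 invalid input, 3 undefined
statistic.

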