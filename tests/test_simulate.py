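"""Birth-death simulation with WGD events, study fixtures, and the
placement-accuracy harness."""

import numpy as np
import pytest
from scipy import stats

import wgdkit as w
from wgdkit.simulate import (
    SimulationConfig,
    accuracy,
    evaluate_placement,
    make_balanced,
    make_caterpillar,
    run_grid,
    simulate_gene_tree,
)
from wgdkit.treecore import MISSING, PRESENT, collect_marks


class TestFixtures:
    @pytest.mark.parametrize("factory", [make_balanced, make_caterpillar])
    @pytest.mark.parametrize("spacing", [1, 2, 3])
    def test_two_marks_one_event_pair(self, factory, spacing):
        root = factory(spacing)
        marks = collect_marks(root)
        assert [m.event_index for m in marks] == [0, 1]
        assert w.find_event_pairs(root) == [w.EventPair(0, 1)]

    @pytest.mark.parametrize("factory", [make_balanced, make_caterpillar])
    def test_marks_are_spacing_speciations_apart(self, factory):
        for spacing in (1, 2, 3):
            root = factory(spacing)
            older, younger = collect_marks(root)
            between = 0
            node = younger.node.parent
            while node is not older.node.parent:
                between += 1
                node = node.parent
            assert between == spacing

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(w.TreeValidationError):
            make_balanced(0)

    def test_fixture_round_trips_through_newick(self, tree_equal):
        root = make_caterpillar(2)
        again = w.parse_newick(w.write_newick(root), role="species")
        assert tree_equal(root, again)


class TestSimulateGeneTree:
    def test_zero_rates_give_full_retention_shape(self):
        sp = w.parse_newick("((a:30,b:30)[&&NHX:W=0:T=45]:30,c:60);",
                            role="species")
        sim = simulate_gene_tree(sp, SimulationConfig(0.0, 0.0, seed=1))
        assert not sim.extinct
        labels = sorted(l.label for l in sim.root.leaves())
        assert labels == ["a1", "a2", "b1", "b2", "c1"]
        assert len(sim.truth) == 1
        evt, node, status = sim.truth[0]
        assert (evt, status) == (0, PRESENT)
        assert sorted(l.species for l in node.leaves()) == ["a", "a", "b", "b"]

    def test_same_seed_reproduces_tree(self):
        sp = make_balanced(1)
        cfg = SimulationConfig(0.005, 0.005, seed=11)
        a = simulate_gene_tree(sp, cfg, np.random.default_rng(11))
        b = simulate_gene_tree(sp, cfg, np.random.default_rng(11))
        if a.extinct:
            assert b.extinct
        else:
            for x, y in zip(a.root.postorder(), b.root.postorder()):
                assert x.label == y.label and x.age == y.age

    def test_zero_loss_leaf_counts_are_conserved(self):
        """Without losses every copy survives: each species carries at least
        2^(#WGDs on its root-to-tip path) gene copies (exactly that many
        when no SSD occurred), and every SSD adds at least one extra leaf."""
        sp = make_balanced(1)
        rng = np.random.default_rng(2)
        cfg = SimulationConfig(ssd_rate=0.003, loss_rate=0.0)
        wgd_path = {"a": 2, "b": 1}  # a sits under events 0 and 1; b under 0
        baseline = sum(
            2 ** wgd_path.get(s, 0) for s in ("a", "b", "c", "d")
        )
        for _ in range(50):
            sim = simulate_gene_tree(sp, cfg, rng)
            per_species = {}
            for leaf in sim.root.leaves():
                per_species[leaf.species] = per_species.get(leaf.species, 0) + 1
            for species in ("a", "b", "c", "d"):
                n_wgd = wgd_path.get(species, 0)
                assert per_species[species] >= 2 ** n_wgd
            total = sum(per_species.values())
            if sim.n_ssd == 0:
                assert total == baseline
            else:
                assert total >= baseline + sim.n_ssd

    def test_truth_present_nodes_have_both_subtrees_extant(self):
        sp = make_caterpillar(2)
        rng = np.random.default_rng(4)
        cfg = SimulationConfig(0.005, 0.008)
        seen_present = 0
        for _ in range(100):
            sim = simulate_gene_tree(sp, cfg, rng)
            observed = (
                set() if sim.extinct
                else {id(n) for n in sim.root.preorder()}
            )
            for evt, node, status in sim.truth:
                assert id(node) in observed
                if status == PRESENT:
                    seen_present += 1
                    assert len(node.children) == 2
                    assert all(c.leaves() for c in node.children)
        assert seen_present > 0

    def test_all_lineages_extinct_gives_sentinel(self):
        sp = w.parse_newick("(a:100,b:100);", role="species")
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(ssd_rate=0.0, loss_rate=0.5)
        sims = [simulate_gene_tree(sp, cfg, rng) for _ in range(20)]
        assert all(s.extinct for s in sims)
        assert all(s.truth == [] for s in sims)

    def test_ssd_counts_poisson_distributed(self):
        """Per-branch SSD counts follow Poisson(rate x length): chi-square
        goodness of fit at alpha = 0.01."""
        sp = w.parse_newick("(a:30,b:30);", role="species")
        lam = 0.002 * 30
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(ssd_rate=0.002, loss_rate=0.0)
        counts = np.array([
            simulate_gene_tree(sp, cfg, rng).ssd_by_branch.get("a", 0)
            for _ in range(1000)
        ])
        observed = np.array([
            np.sum(counts == 0), np.sum(counts == 1), np.sum(counts >= 2)
        ])
        p = np.array([
            stats.poisson.pmf(0, lam),
            stats.poisson.pmf(1, lam),
            1 - stats.poisson.cdf(1, lam),
        ])
        result = stats.chisquare(observed, 1000 * p)
        assert result.pvalue > 0.01


class TestAccuracy:
    def test_perfect_match(self):
        sp = make_balanced(1)
        sim = simulate_gene_tree(sp, SimulationConfig(0, 0, seed=5))
        placements = evaluate_placement(sim, sp)
        correct, called = accuracy(placements, sim)
        assert correct == called == len(sim.truth) == 3

    def test_wrong_node_is_counted_incorrect(self):
        sp = make_balanced(1)
        sim = simulate_gene_tree(sp, SimulationConfig(0, 0, seed=5))
        placements = evaluate_placement(sim, sp)
        # corrupt one truth entry: move it to the root node
        evt, node, status = sim.truth[0]
        sim.truth[0] = (evt, sim.root, status)
        correct, called = accuracy(placements, sim)
        assert called == 3 and correct == 2

    def test_empty_inference_contributes_nothing(self):
        sp = make_balanced(1)
        sim = simulate_gene_tree(sp, SimulationConfig(0, 0, seed=5))
        assert accuracy([], sim) == (0, 0)


class TestRunGrid:
    def test_zero_rates_are_perfectly_recovered(self):
        records = run_grid(
            [("balanced", 1, make_balanced(1))], [(0.0, 0.0)], 25, seed=3
        )
        assert len(records) == 1
        assert records[0].accuracy == 1.0
        assert records[0].called == records[0].correct > 0

    def test_grid_covers_all_conditions_deterministically(self):
        fixtures = [("balanced", 1, make_balanced(1)),
                    ("caterpillar", 1, make_caterpillar(1))]
        grid = [(0.01, 0.01), (0.0, 0.002)]
        a = run_grid(fixtures, grid, 10, seed=9)
        b = run_grid(fixtures, grid, 10, seed=9)
        assert a == b
        assert len(a) == 4
        assert {(r.tree_type, r.ssd_rate, r.loss_rate) for r in a} == {
            ("balanced", 0.01, 0.01), ("balanced", 0.0, 0.002),
            ("caterpillar", 0.01, 0.01), ("caterpillar", 0.0, 0.002),
        }


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(ssd_rate=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(n_trees=0)
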