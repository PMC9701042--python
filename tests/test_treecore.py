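"""Newick/NHX I/O, species-naming conventions and event-pair discovery."""

import pytest
from hypothesis import given, strategies as st

import wgdkit as w
from wgdkit.errors import (
    LeafMappingError,
    NewickParseError,
    TreeValidationError,
)
from wgdkit.treecore import EventPair, collect_marks


class TestParse:
    def test_three_leaf_tree_shape(self):
        root = w.parse_newick("((a:10,b:10):10,c:20);")
        leaves = [l.label for l in root.leaves()]
        internal = [n for n in root.postorder() if not n.is_leaf]
        assert leaves == ["a", "b", "c"]
        assert len(internal) == 2
        assert root.children[0].children[1].length == 10

    def test_wgd_mark_extracted_on_child_node(self):
        root = w.parse_newick(
            "((a:76,b:76)[&&NHX:W=1:T=100]:54,c:130);", role="species"
        )
        marks = collect_marks(root)
        assert len(marks) == 1
        assert marks[0].event_index == 1
        assert marks[0].time == 100.0
        assert marks[0].node is root.children[0]

    def test_malformed_newick_raises_parse_error(self):
        with pytest.raises(NewickParseError):
            w.parse_newick("((a,b)")

    def test_mark_time_outside_branch_interval_rejected(self):
        # branch above (a,b) spans ages (76, 130); T=40 is below it
        with pytest.raises(TreeValidationError, match="outside"):
            w.parse_newick(
                "((a:76,b:76)[&&NHX:W=1:T=40]:54,c:130);", role="species"
            )

    def test_non_ultrametric_species_tree_rejected(self):
        with pytest.raises(TreeValidationError, match="ultrametric"):
            w.parse_newick("((a:10,b:12):10,c:20);", role="species")

    def test_multifurcating_species_tree_rejected(self):
        with pytest.raises(TreeValidationError, match="binary"):
            w.parse_newick("((a:10,b:10,c:10):10,d:20);", role="species")

    def test_underscores_preserved(self):
        root = w.parse_newick("(Phalaenopsis_equestris:1,Oryza_brachyantha:1);")
        assert root.children[0].label == "Phalaenopsis_equestris"


class TestWrite:
    def test_round_trip_simple(self, tree_equal):
        text = "((a:10,b:10):10,c:20);"
        root = w.parse_newick(text)
        assert w.write_newick(root) == text
        assert tree_equal(root, w.parse_newick(w.write_newick(root)))

    def test_round_trip_species_marks(self, tree_equal):
        text = "((a:76,b:76)[&&NHX:W=1:T=100]:54,c:130);"
        root = w.parse_newick(text, role="species")
        again = w.parse_newick(w.write_newick(root), role="species")
        assert tree_equal(root, again)

    def test_gene_wgd_labels_serialized(self):
        root = w.parse_newick("(a1,b1);")
        root.wgd_labels.append(w.WGDLabel(0, "present"))
        out = w.write_newick(root)
        assert "evt=0" in out and "st=P" in out
        again = w.parse_newick(out)
        assert again.wgd_labels == [w.WGDLabel(0, "present")]

    def test_single_leaf_degenerate(self):
        assert w.write_newick(w.parse_newick("a;")) == "a;"


@st.composite
def newick_trees(draw):
    """Random binary trees with integer-ish branch lengths."""
    label_counter = [0]

    def leaf():
        label_counter[0] += 1
        return f"t{label_counter[0]}"

    def build(depth):
        if depth == 0 or draw(st.booleans()):
            return leaf()
        return (build(depth - 1), build(depth - 1))

    shape = (build(3), build(3))

    def fmt(node):
        if isinstance(node, str):
            return f"{node}:{draw(st.integers(1, 50))}"
        return "(" + ",".join(fmt(c) for c in node) + f"):{draw(st.integers(1, 50))}"

    return "(" + ",".join(fmt(c) for c in shape) + ");"


@given(newick_trees())
def test_parse_write_round_trip_is_identity(text):
    root = w.parse_newick(text)
    once = w.write_newick(root)
    assert w.write_newick(w.parse_newick(once)) == once


class TestSpeciesOfLeaf:
    @pytest.mark.parametrize(
        "label,expected", [("a1", "a"), ("b12", "b"), ("Xyz9", "Xyz")]
    )
    def test_suffix_convention(self, label, expected):
        assert w.species_of_leaf(label, "suffix") == expected

    def test_delimiter_convention(self):
        assert (
            w.species_of_leaf(
                "Phalaenopsis_equestris|XP_0001", "delimiter",
                delimiter="|", fld=0,
            )
            == "Phalaenopsis_equestris"
        )

    def test_explicit_map(self):
        assert w.species_of_leaf("g17", {"g17": "a"}) == "a"
        with pytest.raises(LeafMappingError):
            w.species_of_leaf("g18", {"g17": "a"})

    def test_suffix_without_trailing_integer_errors(self):
        with pytest.raises(LeafMappingError, match="abc"):
            w.species_of_leaf("abc", "suffix")


class TestEventPairs:
    def test_nested_marks_give_one_pair(self, species_abcd_marked):
        assert w.find_event_pairs(species_abcd_marked) == [EventPair(0, 1)]

    def test_sibling_lineage_marks_give_no_pair(self):
        root = w.parse_newick(
            "((a[&&NHX:W=0:T=15]:30,b:30):30,"
            "(c[&&NHX:W=1:T=15]:30,d:30):30);",
            role="species",
        )
        assert w.find_event_pairs(root) == []

    def test_three_nested_marks_give_all_ancestor_descendant_pairs(self):
        root = w.parse_newick(
            "(((a[&&NHX:W=2:T=15]:30,b:30)[&&NHX:W=1:T=45]:30,c:60)"
            "[&&NHX:W=0:T=75]:30,d:90);",
            role="species",
        )
        pairs = w.find_event_pairs(root)
        # brute force: every ancestor-descendant mark pair, older first
        marks = collect_marks(root)
        expected = []
        for i, older in enumerate(marks):
            for younger in marks[i + 1:]:
                node = younger.node
                anc = {id(x) for x in node.ancestors()}
                if id(older.node) in anc or older.node is node:
                    expected.append(
                        EventPair(older.event_index, younger.event_index)
                    )
        assert pairs == expected
        assert len(pairs) == 3

    def test_duplicate_event_index_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            w.parse_newick(
                "((a[&&NHX:W=0:T=15]:30,b:30)[&&NHX:W=0:T=45]:30,"
                "(c:30,d:30):30);",
                role="species",
            )


def test_species_set_union_invariant(worked_example):
    """Every internal node's species set is the union of its children's."""
    species, gene = worked_example
    w.lca_reconcile(gene, species)
    for node in gene.postorder():
        if node.children:
            assert node.species_set == frozenset().union(
                *(c.species_set for c in node.children)
            )
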