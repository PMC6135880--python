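import dendropy
import pytest

from amoebahgt.errors import ArgumentError
from amoebahgt.io import OrfRecord
from amoebahgt.pipeline import GeneTaxLabel
from amoebahgt.search import OrthologGroup
from amoebahgt.synteny import (
    SyntenyBlock,
    conservation_matrix,
    genome_tree_from_ortholog_jaccard,
    map_block,
    select_viral_scaffolds,
)


def _orfs(scaffold, gene_ids, start=1):
    out = []
    pos = start
    for g in gene_ids:
        out.append(OrfRecord(g, scaffold, pos, pos + 302, "+", 0, "M" * 100))
        pos += 400
    return out


def _viral_labels(gene_ids):
    from amoebahgt.align import align_pair

    hit = align_pair("MKLVTA" * 20, "MKLVTA" * 20)
    return [GeneTaxLabel(g, "virus", "fam", hit) for g in gene_ids]


class TestSelection:
    def test_three_viral_genes_selected(self):
        orfs = _orfs("s1", ["a", "b", "c"])
        blocks = select_viral_scaffolds(orfs, _viral_labels(["a", "b", "c"]))
        assert len(blocks) == 1
        assert blocks[0].gene_ids == ("a", "b", "c")

    def test_two_viral_genes_not_selected(self):
        orfs = _orfs("s1", ["a", "b"])
        assert select_viral_scaffolds(orfs, _viral_labels(["a", "b"])) == []

    def test_gene_order_follows_coordinates(self):
        orfs = list(reversed(_orfs("s1", ["a", "b", "c", "d"])))
        blocks = select_viral_scaffolds(orfs, _viral_labels(["a", "b", "c", "d"]))
        assert blocks[0].gene_ids == ("a", "b", "c", "d")


class TestMapBlock:
    BLOCK = SyntenyBlock("s1", ("a", "b", "c", "d"))

    def test_identical_target(self):
        target = _orfs("t1", ["ta", "tb", "tc", "td"])
        rbh = [("a", "ta"), ("b", "tb"), ("c", "tc"), ("d", "td")]
        res = map_block(self.BLOCK, target, rbh)
        assert res.conserved_count == 4
        assert res.order_score == 1.0
        assert res.matched_scaffolds == ("t1",)

    def test_reversed_target_counts_as_collinear(self):
        target = _orfs("t1", ["td", "tc", "tb", "ta"])
        rbh = [("a", "ta"), ("b", "tb"), ("c", "tc"), ("d", "td")]
        assert map_block(self.BLOCK, target, rbh).order_score == 1.0

    def test_genes_scattered_across_scaffolds(self):
        target = (
            _orfs("t1", ["ta", "tc"]) + _orfs("t2", ["tb"]) + _orfs("t3", ["td"])
        )
        rbh = [("a", "ta"), ("b", "tb"), ("c", "tc"), ("d", "td")]
        res = map_block(self.BLOCK, target, rbh)
        assert res.conserved_count == 4
        assert res.order_score == 0.5  # best single-scaffold run: a,c on t1
        assert res.matched_scaffolds == ("t1", "t2", "t3")

    def test_shuffled_order_caps_score(self):
        target = _orfs("t1", ["tc", "ta", "td", "tb"])
        rbh = [("a", "ta"), ("b", "tb"), ("c", "tc"), ("d", "td")]
        res = map_block(self.BLOCK, target, rbh)
        assert res.conserved_count == 4
        assert res.order_score < 1.0

    def test_absent_genes(self):
        res = map_block(self.BLOCK, _orfs("t1", ["x"]), [])
        assert res.conserved_count == 0
        assert res.order_score == 0.0


class TestConservationMatrix:
    def test_totals_row(self):
        blocks = [SyntenyBlock("s1", ("a", "b", "c")), SyntenyBlock("s2", ("d", "e", "f"))]
        from amoebahgt.synteny import ConservationResult

        results = {
            "full": {
                "s1": ConservationResult(3, 1.0, ("t",)),
                "s2": ConservationResult(3, 1.0, ("t",)),
            },
            "partial": {"s1": ConservationResult(2, 0.5, ("t",))},
            "none": {},
        }
        df = conservation_matrix(blocks, results, ["full", "partial", "none"])
        assert df.loc["total", "full"] == 6
        assert df.loc["total", "partial"] == 2
        assert df.loc["total", "none"] == 0
        assert df.loc["s2", "partial"] == 0


class TestGenomeTree:
    def _groups(self, memberships):
        return [
            OrthologGroup(f"OG{i}", frozenset((g, f"{g}_x{i}") for g in genomes))
            for i, genomes in enumerate(memberships)
        ]

    def test_identical_membership_zero_distance(self):
        groups = self._groups([["A", "B", "C"]] * 5)
        nwk = genome_tree_from_ortholog_jaccard(groups, ["A", "B", "C"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert tree.length() == pytest.approx(0.0)

    def test_fewer_than_three_genomes_rejected(self):
        with pytest.raises(ArgumentError):
            genome_tree_from_ortholog_jaccard([], ["A", "B"])

    def test_nested_subset_design(self):
        """A/B share almost everything, C/D share almost everything, and the
        two pairs share little: the tree splits AB|CD."""
        memberships = (
            [["A", "B"]] * 8 + [["C", "D"]] * 8 + [["A", "B", "C", "D"]] * 2
        )
        nwk = genome_tree_from_ortholog_jaccard(self._groups(memberships), ["A", "B", "C", "D"])
        tns = dendropy.TaxonNamespace()
        tree = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
        tree.encode_bipartitions()
        splits = {
            frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            for node in tree.preorder_node_iter()
            if not node.is_leaf()
        }
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits
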