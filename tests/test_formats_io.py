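"""Parsers and writers: Newick, OrthoXML, gene orders, OBO/GAF."""

import pytest

from paleohog.formats_io import (
    parse_gaf,
    parse_gene_orders,
    parse_hogs,
    parse_ontology,
    parse_species_tree,
    serialize_gene_orders,
    serialize_species_tree,
)
from paleohog.model import NewickParseError, ValidationError

from conftest import TINY_NEWICK, TINY_OBO, make_orthoxml


class TestSpeciesTree:
    def test_structure(self, tiny_tree):
        assert sorted(tiny_tree.leaf_names) == ["A", "B", "C"]
        assert set(tiny_tree.internal_names()) == {"AB", "ROOT"}
        assert tiny_tree.parent_of("AB") == "ROOT"
        assert tiny_tree.clade_leaves("AB") == {"A", "B"}
        assert tiny_tree.lca(["A", "C"]) == "ROOT"
        assert tiny_tree.lca(["A", "B"]) == "AB"
        assert tiny_tree.is_ancestor_or_equal("ROOT", "A")
        assert not tiny_tree.is_ancestor_or_equal("AB", "C")

    def test_single_leaf_rejected(self):
        with pytest.raises(ValidationError):
            parse_species_tree("(A);")

    def test_malformed_rejected(self):
        with pytest.raises(NewickParseError):
            parse_species_tree("((A,B,;")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            parse_species_tree("((A,B)X,(C,D)X)R;")

    def test_round_trip(self):
        text = serialize_species_tree(parse_species_tree(TINY_NEWICK))
        assert text == TINY_NEWICK
        again = serialize_species_tree(parse_species_tree(text))
        assert again == text

    def test_auto_labels_preorder(self):
        tree = parse_species_tree("((A,B),(C,D));")
        assert tree.root.name == "N1"
        assert [n.name for n in tree.preorder() if not n.is_leaf] == ["N1", "N2", "N3"]

    def test_unary_chain_collapsed(self):
        tree = parse_species_tree("(((A,B))X,C)R;")
        assert set(tree.internal_names()) == {"X", "R"}
        assert tree.node("X").children[0].name == "A"


class TestOrthoXML:
    def test_lca_level_when_no_taxrange(self, tiny_tree):
        xml = make_orthoxml(
            [("A", "a1"), ("B", "b1")],
            '<orthologGroup><geneRef id="1"/><geneRef id="2"/></orthologGroup>',
        )
        forest = parse_hogs(xml, tiny_tree)
        assert forest.roots[0].level == "AB"

    def test_duplication_suffixes(self, tiny_forest):
        ids = {n.hog_id for r in tiny_forest.roots for n in r.iter_nodes()
               if n.kind == "ortholog-group"}
        assert {"HOG:T001", "HOG:T001.1a", "HOG:T001.1b"} <= ids

    def test_member_partition(self, tiny_forest):
        total = sum(len(r.members()) for r in tiny_forest.roots)
        assert total == tiny_forest.n_genes() == 7

    def test_empty_group_rejected(self, tiny_tree):
        xml = make_orthoxml([("A", "a1")], "<orthologGroup></orthologGroup>")
        with pytest.raises(ValidationError):
            parse_hogs(xml, tiny_tree)

    def test_unknown_species_rejected(self, tiny_tree):
        xml = make_orthoxml(
            [("Z", "z1"), ("A", "a1")],
            '<orthologGroup><geneRef id="1"/><geneRef id="2"/></orthologGroup>',
        )
        with pytest.raises(ValidationError, match="Z"):
            parse_hogs(xml, tiny_tree)

    def test_default_root_ids(self, tiny_tree):
        xml = make_orthoxml(
            [("A", "a1"), ("B", "b1")],
            '<orthologGroup><geneRef id="1"/><geneRef id="2"/></orthologGroup>',
        )
        forest = parse_hogs(xml, tiny_tree)
        assert forest.roots[0].hog_id == "HOG:R1"


class TestGeneOrders:
    def test_gff3_coordinates_and_species(self):
        gff = "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n" \
              "chr1\tsrc\tgene\t11\t40\t.\t-\t.\tID=g2\n"
        (genome,) = parse_gene_orders(gff, format="gff3", species="A")
        genes = {g.gene_id: g for g in genome.genes()}
        assert genes["g1"].start == 100  # 1-based inclusive -> 0-based half-open
        assert genes["g2"].rank == 0 and genes["g1"].rank == 1

    def test_tsv_unsorted_input_ranked_by_start(self):
        tsv = "A\tchr1\t100\tg1\nA\tchr1\t50\tg2\n"
        (genome,) = parse_gene_orders(tsv)
        ranks = {g.gene_id: g.rank for g in genome.genes()}
        assert ranks == {"g2": 0, "g1": 1}

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValidationError):
            parse_gene_orders("A\tchr1\t1\tg1\nA\tchr2\t5\tg1\n")

    def test_round_trip(self, null_sim):
        out, *_ = null_sim
        genomes = parse_gene_orders(out.gene_orders_tsv)
        text = serialize_gene_orders(genomes)
        again = parse_gene_orders(text)
        assert serialize_gene_orders(again) == text


class TestOntologyAndGaf:
    def test_alt_id_resolves(self, tiny_ontology):
        assert tiny_ontology.resolve("GO:0000001") == "GO:0000003"

    def test_part_of_is_parent(self, tiny_ontology):
        assert "GO:0000003" in tiny_ontology.ancestors("GO:0000004")

    def test_obsolete_flagged(self, tiny_ontology):
        assert tiny_ontology.term("GO:0000099").obsolete

    def test_cycle_rejected(self):
        obo = TINY_OBO.replace(
            "id: GO:0000002\nname: branch A\nnamespace: biological_process\n"
            "is_a: GO:0008150 ! root",
            "id: GO:0000002\nname: branch A\nnamespace: biological_process\n"
            "is_a: GO:0000005 ! cycle",
        )
        with pytest.raises(ValidationError, match="cycle"):
            parse_ontology(obo)

    def _gaf(self, rows):
        header = "!gaf-version: 2.2\n"
        return header + "\n".join(
            "\t".join(["db", subj, subj, qual, term, "REF", ev, "", "P", "", "",
                       "protein", "taxon:0", "20240101", "db", "", ""])
            for subj, qual, term, ev in rows
        ) + "\n"

    def test_nd_and_not_dropped_unknown_skipped(self, tiny_ontology):
        text = self._gaf([
            ("g1", "", "GO:0000005", "IEA"),
            ("g1", "NOT", "GO:0000006", "IEA"),
            ("g2", "", "GO:0000004", "ND"),
            ("g3", "", "GO:9999999", "IEA"),
        ])
        res = parse_gaf(text, tiny_ontology)
        assert len(res.table) == 1
        assert res.n_dropped_not == 1 and res.n_dropped_nd == 1
        assert res.n_skipped_unknown == 1

    def test_redundant_ancestor_removed(self, tiny_ontology):
        # GO:0000004 is an ancestor of GO:0000005 -> only the leaf survives
        text = self._gaf([
            ("g1", "", "GO:0000005", "IEA"),
            ("g1", "", "GO:0000004", "IEA"),
        ])
        res = parse_gaf(text, tiny_ontology)
        assert [(r.subject_id, r.term_id) for r in res.table.rows] == [
            ("g1", "GO:0000005")
        ]

    def test_no_subject_keeps_term_and_its_ancestor(self, mixed_sim):
        _, _, _, _, ontology, gaf = mixed_sim
        for subject, terms in gaf.table.subject_terms().items():
            for t in terms:
                assert not (ontology.ancestors(t) & terms), (subject, t)
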