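"""Ancestral gene content: level extraction, completeness, branch events."""

from fractions import Fraction

import pytest

from paleohog.formats_io import parse_hogs, parse_species_tree
from paleohog.hog_levels import (
    ancestral_genome,
    classify_events,
    completeness_score,
    filter_by_completeness,
    hogs_at_level,
)
from paleohog.model import ValidationError

from conftest import make_orthoxml


class TestHogsAtLevel:
    def test_restriction_to_clade(self, tiny_tree, tiny_forest):
        genes = hogs_at_level(tiny_forest, tiny_tree, "AB")
        fam1 = [g for g in genes if g.root_hog_id == "HOG:T001"]
        # the duplication below ROOT splits the family into two AB genes
        assert sorted(g.hog_id for g in fam1) == ["HOG:T001.1a", "HOG:T001.1b"]
        for g in fam1:
            assert all(sp in {"A", "B"} for _, sp in g.members)

    def test_root_level_counts_whole_family(self, tiny_tree, tiny_forest):
        genes = hogs_at_level(tiny_forest, tiny_tree, "ROOT")
        by_id = {g.hog_id: g for g in genes}
        assert set(by_id) == {"HOG:T001", "HOG:T002"}
        assert by_id["HOG:T001"].n_species_present == 3
        assert by_id["HOG:T002"].n_species_present == 2  # C and A only

    def test_family_absent_from_clade_contributes_nothing(self, tiny_tree):
        xml = make_orthoxml(
            [("C", "c1"), ("C", "c2")],
            '<orthologGroup><property name="TaxRange" value="ROOT"/>'
            '<geneRef id="1"/><geneRef id="2"/></orthologGroup>',
        )
        forest = parse_hogs(xml, tiny_tree)
        assert hogs_at_level(forest, tiny_tree, "AB") == []

    def test_leaf_level_rejected(self, tiny_tree, tiny_forest):
        with pytest.raises(ValidationError, match="extant"):
            hogs_at_level(tiny_forest, tiny_tree, "A")

    def test_all_returned_completeness_positive(self, mixed_sim):
        _, tree, forest, *_ = mixed_sim
        for level in tree.internal_names():
            for g in hogs_at_level(forest, tree, level):
                assert g.completeness > 0


class TestCompleteness:
    def test_exact_ratio(self, tiny_tree, tiny_forest):
        genes = {g.hog_id: g for g in hogs_at_level(tiny_forest, tiny_tree, "ROOT")}
        assert genes["HOG:T002"].completeness == Fraction(2, 3)
        assert completeness_score(genes["HOG:T002"], tiny_tree) == Fraction(2, 3)
        assert genes["HOG:T001"].completeness == 1

    def test_filter_keeps_at_threshold(self, tiny_tree, tiny_forest):
        genes = hogs_at_level(tiny_forest, tiny_tree, "ROOT")
        assert filter_by_completeness(genes, 2 / 3) == genes
        assert filter_by_completeness(genes, 0.9) == [
            g for g in genes if g.completeness == 1
        ]

    def test_three_of_ten_species(self):
        newick = "(" + ",".join(f"S{i}" for i in range(10)) + ")R;"
        tree = parse_species_tree(newick)
        xml = make_orthoxml(
            [("S0", "g0"), ("S1", "g1"), ("S2", "g2")],
            '<orthologGroup><property name="TaxRange" value="R"/>'
            '<geneRef id="1"/><geneRef id="2"/><geneRef id="3"/></orthologGroup>',
        )
        forest = parse_hogs(xml, tree)
        (gene,) = hogs_at_level(forest, tree, "R")
        assert gene.completeness == Fraction(3, 10)


class TestEvents:
    def test_retained_duplicated_gained_lost(self, tiny_tree):
        xml = make_orthoxml(
            [("A", "r1"), ("B", "r2"), ("C", "r3"),          # retained family
             ("A", "d1"), ("B", "d2"), ("A", "d3"), ("B", "d4"), ("C", "d5"),
             ("A", "g1"), ("B", "g2"),                        # gained at AB
             ("C", "l1"), ("C", "l2")],                       # lost on ROOT->AB
            """
            <orthologGroup id="HOG:RET"><property name="TaxRange" value="ROOT"/>
              <geneRef id="3"/>
              <orthologGroup><geneRef id="1"/><geneRef id="2"/></orthologGroup>
            </orthologGroup>
            <orthologGroup id="HOG:DUP"><property name="TaxRange" value="ROOT"/>
              <geneRef id="8"/>
              <paralogGroup>
                <orthologGroup><geneRef id="4"/><geneRef id="5"/></orthologGroup>
                <orthologGroup><geneRef id="6"/><geneRef id="7"/></orthologGroup>
              </paralogGroup>
            </orthologGroup>
            <orthologGroup id="HOG:GAIN"><property name="TaxRange" value="AB"/>
              <geneRef id="9"/><geneRef id="10"/>
            </orthologGroup>
            <orthologGroup id="HOG:LOSS"><property name="TaxRange" value="ROOT"/>
              <geneRef id="11"/><geneRef id="12"/>
            </orthologGroup>
            """,
        )
        forest = parse_hogs(xml, tiny_tree)
        events, lost = classify_events(forest, tiny_tree, "AB", "ROOT")
        assert events["HOG:RET"] == "retained"
        assert events["HOG:DUP.1a"] == "duplicated"
        assert events["HOG:DUP.1b"] == "duplicated"
        assert events["HOG:GAIN"] == "gained"
        assert lost == ["HOG:LOSS"]

    def test_single_surviving_copy_of_duplication_is_retained(self, tiny_tree):
        # duplication below ROOT but one copy leaves no AB descendant
        xml = make_orthoxml(
            [("A", "a1"), ("B", "b1"), ("C", "c1"), ("C", "c2")],
            """
            <orthologGroup id="HOG:X"><property name="TaxRange" value="ROOT"/>
              <paralogGroup>
                <orthologGroup><geneRef id="1"/><geneRef id="2"/></orthologGroup>
                <orthologGroup><geneRef id="3"/><geneRef id="4"/></orthologGroup>
              </paralogGroup>
            </orthologGroup>
            """,
        )
        forest = parse_hogs(xml, tiny_tree)
        events, lost = classify_events(forest, tiny_tree, "AB", "ROOT")
        assert list(events.values()) == ["retained"] and lost == []

    def test_non_ancestor_parent_rejected(self, tiny_tree, tiny_forest):
        with pytest.raises(ValidationError):
            classify_events(tiny_forest, tiny_tree, "ROOT", "AB")

    def test_every_parent_gene_accounted_once(self, mixed_sim):
        """Conservation: each parent-level HOG is hit by retained/duplicated
        descendants or is lost; each level HOG is labeled exactly once."""
        _, tree, forest, *_ = mixed_sim
        for level in tree.internal_names():
            parent = tree.parent_of(level)
            if parent is None:
                continue
            events, lost = classify_events(forest, tree, level, parent)
            level_ids = {g.hog_id for g in hogs_at_level(forest, tree, level)}
            assert set(events) == level_ids
            parent_ids = {g.hog_id for g in hogs_at_level(forest, tree, parent)}
            assert set(lost) <= parent_ids


class TestAncestralGenome:
    def test_default_parent_is_closest_ancestor(self, tiny_tree, tiny_forest):
        genome = ancestral_genome(tiny_forest, tiny_tree, "AB")
        assert genome.parent_level == "ROOT"
        assert all(g.event in {"retained", "duplicated", "gained"} for g in genome.genes)

    def test_completeness_filter_applied(self, tiny_tree, tiny_forest):
        genome = ancestral_genome(tiny_forest, tiny_tree, "ROOT", min_completeness=0.9)
        assert all(g.completeness >= 0.9 for g in genome.genes)
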