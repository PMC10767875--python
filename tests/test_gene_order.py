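"""Adjacency parsimony, contig linearization, synteny windows."""

import random

import networkx as nx
import pytest

from paleohog.formats_io import parse_gene_orders, parse_hogs, parse_species_tree
from paleohog.gene_order import (
    AdjacencyGraph,
    ancestral_contigs,
    build_adjacency_graph,
    linearize,
    max_weight_linear_forest,
    project_genomes,
    synteny_window,
    ProjectedGenome,
)
from paleohog.hog_levels import hogs_at_level

from conftest import make_orthoxml


def _graph(edges) -> AdjacencyGraph:
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return AdjacencyGraph("L", g)


def _contig_weight(g: nx.Graph, contigs) -> int:
    return sum(
        g[a][b]["weight"]
        for c in contigs
        for a, b in zip(c.hog_ids, c.hog_ids[1:])
    )


def brute_force_weight(graph: nx.Graph) -> int:
    """Independent oracle: maximum-weight linear forest by include/exclude
    recursion over edges with degree/cycle feasibility."""
    edges = sorted((tuple(sorted((u, v))), w) for u, v, w in graph.edges(data="weight"))
    deg = {n: 0 for n in graph.nodes}
    parent = {n: n for n in graph.nodes}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    best = 0

    def rec(i, w):
        nonlocal best
        if i == len(edges):
            best = max(best, w)
            return
        rec(i + 1, w)
        (u, v), ew = edges[i]
        if deg[u] < 2 and deg[v] < 2 and find(u) != find(v):
            ru, rv = find(u), find(v)
            parent[ru] = rv
            deg[u] += 1
            deg[v] += 1
            rec(i + 1, w + ew)
            parent[ru] = ru
            deg[u] -= 1
            deg[v] -= 1

    rec(0, 0)
    return best


class TestProjection:
    def test_unmapped_gene_closes_gap(self, tiny_tree):
        xml = make_orthoxml(
            [("A", "g1"), ("B", "h1"), ("A", "g2"), ("B", "h2")],
            """
            <orthologGroup id="HOG:P1"><property name="TaxRange" value="AB"/>
              <geneRef id="1"/><geneRef id="2"/></orthologGroup>
            <orthologGroup id="HOG:P2"><property name="TaxRange" value="AB"/>
              <geneRef id="3"/><geneRef id="4"/></orthologGroup>
            """,
        )
        forest = parse_hogs(xml, tiny_tree)
        genomes = parse_gene_orders(
            "A\tc\t0\tg1\nA\tc\t10\tgx\nA\tc\t20\tg2\nB\tc\t0\th1\nB\tc\t10\th2\n"
        )
        projected = project_genomes(genomes, forest, tiny_tree, "AB")
        assert [p.contigs for p in projected] == [
            {"c": ["HOG:P1", "HOG:P2"]},
            {"c": ["HOG:P1", "HOG:P2"]},
        ]
        graph = build_adjacency_graph(projected, "AB")
        assert graph.edge_weight("HOG:P1", "HOG:P2") == 2

    def test_fully_unmapped_contig_dropped(self, tiny_tree, tiny_forest):
        genomes = parse_gene_orders("A\tcX\t0\tzz1\nA\tcX\t5\tzz2\n")
        # genes zz* belong to no family at all
        projected = project_genomes(genomes, tiny_forest, tiny_tree, "AB")
        assert projected[0].contigs == {}


class TestAdjacencyCounting:
    def test_counts_per_occurrence_and_symmetry(self):
        projected = [
            ProjectedGenome("A", {"c": ["H1", "H2", "H3"]}),
            ProjectedGenome("B", {"c": ["H3", "H2", "H1"]}),
        ]
        graph = build_adjacency_graph(projected, "L")
        assert graph.edge_weight("H1", "H2") == 2  # unordered
        assert graph.edge_weight("H2", "H3") == 2

    def test_tandem_pair_skipped(self):
        graph = build_adjacency_graph([ProjectedGenome("A", {"c": ["H1", "H1", "H2"]})], "L")
        assert not graph.graph.has_edge("H1", "H1")
        assert graph.edge_weight("H1", "H2") == 1

    def test_weight_sum_invariant(self, mixed_sim):
        """Total edge weight equals consecutive pairs minus tandem skips."""
        _, tree, forest, genomes, *_ = mixed_sim
        level = tree.root.name
        projected = project_genomes(genomes, forest, tree, level)
        graph = build_adjacency_graph(projected, level)
        expected = 0
        for p in projected:
            for hogs in p.contigs.values():
                expected += sum(1 for a, b in zip(hogs, hogs[1:]) if a != b)
        assert graph.total_weight() == expected


class TestLinearize:
    def test_path_graph_returned_whole(self):
        contigs = linearize(_graph([("H1", "H2", 5), ("H2", "H3", 4)]))
        assert [c.hog_ids for c in contigs] == [["H1", "H2", "H3"]]

    def test_star_keeps_two_heaviest_arms(self):
        contigs = linearize(
            _graph([("H0", "H1", 3), ("H0", "H2", 2), ("H0", "H3", 1)])
        )
        assert [c.hog_ids for c in contigs] == [["H1", "H0", "H2"], ["H3"]]

    def test_triangle_cycle_broken_into_path(self):
        contigs = linearize(
            _graph([("H1", "H2", 1), ("H2", "H3", 1), ("H1", "H3", 1)])
        )
        assert len(contigs) == 1 and contigs[0].length == 3
        assert contigs[0].was_circular

    def test_min_weight_drops_light_edges(self):
        contigs = linearize(_graph([("H1", "H2", 5), ("H2", "H3", 1)]), min_weight=2)
        assert [c.hog_ids for c in contigs] == [["H1", "H2"], ["H3"]]

    def test_degrees_le_two_and_acyclic(self, mixed_sim):
        _, tree, forest, genomes, *_ = mixed_sim
        contigs, graph = ancestral_contigs(genomes, forest, tree, tree.root.name)
        seen = set()
        for c in contigs:
            assert len(set(c.hog_ids)) == len(c.hog_ids)  # a simple path
            seen.update(c.hog_ids)
        assert seen == set(graph.graph.nodes)

    def test_matches_brute_force_on_small_random_graphs(self):
        rng = random.Random(42)
        for _ in range(40):
            n = rng.randint(2, 7)
            g = nx.Graph()
            nodes = [f"H{i}" for i in range(n)]
            g.add_nodes_from(nodes)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        g.add_edge(nodes[i], nodes[j], weight=rng.randint(1, 9))
            contigs = linearize(AdjacencyGraph("L", g))
            assert _contig_weight(g, contigs) == brute_force_weight(g)

    def test_exact_forest_is_valid_linear_forest(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: f"H{i}" for i in range(6)})
        for u, v in g.edges:
            g[u][v]["weight"] = 1 + (hash((min(u, v), max(u, v))) % 5)
        forest = max_weight_linear_forest(g)
        fg = nx.Graph(tuple(e) for e in forest)
        assert all(d <= 2 for _, d in fg.degree())
        assert nx.is_forest(fg)

    def test_planted_order_recovered(self, null_sim):
        out, tree, forest, genomes, *_ = null_sim
        for level in tree.internal_names():
            contigs, _ = ancestral_contigs(genomes, forest, tree, level)
            (truth,) = out.ground_truth.order[level]
            assert len(contigs) == 1
            got = contigs[0].hog_ids
            assert got == truth or got == truth[::-1]


class TestSynteny:
    def test_window_truncated_at_contig_end(self, null_sim):
        out, tree, forest, genomes, *_ = null_sim
        level = tree.root.name
        (truth,) = out.ground_truth.order[level]
        focal = truth[2]  # three genes from the left end
        view = synteny_window(focal, level, forest, tree, genomes, window=5)
        top = view.rows[0]
        pos = [e.id for e in top.entries].index(focal)
        assert pos in (2, len(top.entries) - 3)  # orientation-free truncation
        assert len(top.entries) == 2 + 1 + 5

    def test_collapse_replaces_leaf_rows(self, null_sim):
        out, tree, forest, genomes, *_ = null_sim
        level = tree.root.name
        focal = out.ground_truth.order[level][0][5]
        child = tree.root.children[0].name
        full = synteny_window(focal, level, forest, tree, genomes)
        collapsed = synteny_window(
            focal, level, forest, tree, genomes, collapsed={child}
        )
        leaf_rows = {r.taxon for r in full.rows if r.kind == "extant"}
        assert tree.clade_leaves(child) <= leaf_rows
        taxa = [r.taxon for r in collapsed.rows]
        assert child in taxa
        assert not (set(taxa) & tree.clade_leaves(child))

    def test_unrelated_neighbor_is_grey(self, tiny_tree):
        # B's neighborhood has an extra B-only gene next to the focal one
        xml = make_orthoxml(
            [("A", "g1"), ("B", "h1"), ("A", "g2"), ("B", "h2")],
            """
            <orthologGroup id="HOG:P1"><property name="TaxRange" value="AB"/>
              <geneRef id="1"/><geneRef id="2"/></orthologGroup>
            <orthologGroup id="HOG:P2"><property name="TaxRange" value="AB"/>
              <geneRef id="3"/><geneRef id="4"/></orthologGroup>
            """,
        )
        forest = parse_hogs(xml, tiny_tree)
        genomes = parse_gene_orders(
            "A\tc\t0\tg1\nA\tc\t10\tg2\n"
            "B\tc\t0\th1\nB\tc\t10\thx\nB\tc\t20\th2\n"
        )
        view = synteny_window("HOG:P1", "AB", forest, tiny_tree, genomes)
        b_row = next(r for r in view.rows if r.taxon == "B")
        colors = {e.id: e.color_class for e in b_row.entries}
        assert colors["hx"] is None  # no inferred homology -> grey
        assert colors["h1"] == "HOG:P1" and colors["h2"] == "HOG:P2"

    def test_every_row_contains_focal_family(self, mixed_sim):
        _, tree, forest, genomes, *_ = mixed_sim
        level = tree.root.name
        genes = hogs_at_level(forest, tree, level)
        focal = genes[0].hog_id
        view = synteny_window(focal, level, forest, tree, genomes)
        for row in view.rows:
            assert any(e.is_focal for e in row.entries), row.taxon
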