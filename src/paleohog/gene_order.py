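"""Ancestral gene order: adjacency parsimony, contig linearization, synteny windows.

Extant gene orders are projected onto the level-specific HOGs; every
consecutive pair of projected genes is one supporting context for the
adjacency of two ancestral genes.  The weighted adjacency graph is then
linearized into ancestral contigs -- maximal paths, reported by decreasing
length -- by selecting a maximum-weight linear subgraph (every node of degree
at most two, no cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx

from .hog_levels import AncestralGene, hogs_at_level
from .model import ExtantGenome, HOGForest, HOGNode, SpeciesTree, ValidationError

# components up to this size are linearized by exact dynamic programming;
# larger ones fall back to the greedy heuristic
EXACT_MAX_NODES = 9

DEFAULT_WINDOW = 5


@dataclass
class ProjectedGenome:
    """One extant genome with genes replaced by their level-HOG ids."""

    species: str
    contigs: dict[str, list[str]]


@dataclass
class AdjacencyGraph:
    """Weighted adjacencies between ancestral genes at one level."""

    level: str
    graph: nx.Graph

    def edge_weight(self, u: str, v: str) -> int:
        return self.graph[u][v]["weight"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.graph.edges(data="weight"))


@dataclass
class AncestralContig:
    hog_ids: list[str]
    was_circular: bool = False

    @property
    def length(self) -> int:
        return len(self.hog_ids)


def gene_to_hog_map(genes: list[AncestralGene]) -> dict[str, str]:
    """gene_id -> level HOG id over the clade members of the ancestral genes."""
    mapping: dict[str, str] = {}
    for ag in genes:
        for gene_id, _ in ag.members:
            mapping[gene_id] = ag.hog_id
    return mapping


def project_genomes(
    genomes: list[ExtantGenome],
    forest: HOGForest,
    tree: SpeciesTree,
    level: str,
    level_genes: list[AncestralGene] | None = None,
) -> list[ProjectedGenome]:
    """Map each extant gene to its level HOG; unmapped genes are removed,
    closing the gap so that their neighbors become adjacent."""
    if level_genes is None:
        level_genes = hogs_at_level(forest, tree, level)
    mapping = gene_to_hog_map(level_genes)
    clade = tree.clade_leaves(level)
    out = []
    for genome in genomes:
        if genome.species not in clade:
            continue
        contigs = {}
        for contig, records in genome.contigs.items():
            projected = [mapping[g.gene_id] for g in records if g.gene_id in mapping]
            if projected:
                contigs[contig] = projected
        out.append(ProjectedGenome(genome.species, contigs))
    return out


def build_adjacency_graph(
    projected: list[ProjectedGenome],
    level: str,
    level_genes: list[AncestralGene] | None = None,
) -> AdjacencyGraph:
    """Count one supporting context per consecutive projected pair, per
    occurrence (a pair seen on two contigs of one genome counts twice).
    Tandem pairs (the same HOG twice in a row) are skipped: no self-edges."""
    graph = nx.Graph()
    if level_genes:
        for ag in level_genes:
            graph.add_node(ag.hog_id, completeness=float(ag.completeness), size=ag.n_members)
    for pg in projected:
        for hogs in pg.contigs.values():
            graph.add_nodes_from(hogs)
            for u, v in zip(hogs, hogs[1:]):
                if u == v:
                    continue
                if graph.has_edge(u, v):
                    graph[u][v]["weight"] += 1
                else:
                    graph.add_edge(u, v, weight=1)
    return AdjacencyGraph(level=level, graph=graph)


# ---------------------------------------------------------------------------
# Linearization


def _greedy_linear_forest(graph: nx.Graph) -> set[frozenset]:
    """Accept edges by descending weight (ties: lexicographically smaller
    pair first) while both endpoints keep degree < 2 and no cycle forms."""
    edges = sorted(
        ((tuple(sorted((u, v))), w) for u, v, w in graph.edges(data="weight")),
        key=lambda e: (-e[1], e[0]),
    )
    degree: dict[str, int] = {}
    uf: dict[str, str] = {n: n for n in graph.nodes}

    def find(x: str) -> str:
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    accepted: set[frozenset] = set()
    for (u, v), _w in edges:
        if degree.get(u, 0) >= 2 or degree.get(v, 0) >= 2:
            continue
        ru, rv = find(u), find(v)
        if ru == rv:
            continue
        uf[ru] = rv
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
        accepted.add(frozenset((u, v)))
    return accepted


def max_weight_linear_forest(graph: nx.Graph) -> set[frozenset]:
    """Exact maximum-weight linear forest (vertex-disjoint paths) of a small
    graph, by dynamic programming over vertex subsets.  Among equal-weight
    optima, the lexicographically smallest sorted edge list is returned, so
    the result is deterministic (this is the tie rule that decides, e.g.,
    which edge of an all-equal-weight cycle is dropped)."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in range(n)]
    weight: dict[tuple[int, int], int] = {}
    for u, v, w in graph.edges(data="weight"):
        iu, iv = idx[u], idx[v]
        adj[iu].append(iv)
        adj[iv].append(iu)
        weight[(min(iu, iv), max(iu, iv))] = w
    for neigh in adj:
        neigh.sort()

    def canonical(edges: frozenset) -> tuple:
        return tuple(sorted(tuple(sorted(e)) for e in edges))

    @lru_cache(maxsize=None)
    def best(mask: int) -> tuple[int, frozenset]:
        if mask == 0:
            return 0, frozenset()
        v = (mask & -mask).bit_length() - 1
        best_w, best_edges = None, None

        def consider(path_w: int, path_nodes: int, path_edges: frozenset) -> None:
            nonlocal best_w, best_edges
            rest_w, rest_edges = best(mask & ~path_nodes)
            total = path_w + rest_w
            edges = path_edges | rest_edges
            if (
                best_w is None
                or total > best_w
                or (total == best_w and canonical(edges) < canonical(best_edges))
            ):
                best_w, best_edges = total, edges

        # enumerate simple paths containing v inside mask: a left arm and a
        # right arm growing out of v; mirror duplicates removed by requiring
        # the left endpoint index not to exceed the right endpoint index
        def grow_right(end: int, used: int, arm_w: int, arm_edges: frozenset, left_end: int):
            if left_end <= end:
                consider(arm_w, used, arm_edges)
            for nxt in adj[end]:
                if mask >> nxt & 1 and not used >> nxt & 1:
                    e = (min(end, nxt), max(end, nxt))
                    grow_right(nxt, used | 1 << nxt, arm_w + weight[e],
                               arm_edges | {frozenset((nodes[end], nodes[nxt]))},
                               left_end)

        def grow_left(end: int, used: int, arm_w: int, arm_edges: frozenset):
            grow_right(v, used, arm_w, arm_edges, end)
            for nxt in adj[end]:
                if mask >> nxt & 1 and not used >> nxt & 1:
                    e = (min(end, nxt), max(end, nxt))
                    grow_left(nxt, used | 1 << nxt, arm_w + weight[e],
                              arm_edges | {frozenset((nodes[end], nodes[nxt]))})

        grow_left(v, 1 << v, 0, frozenset())
        return best_w, best_edges

    _, edges = best((1 << n) - 1)
    best.cache_clear()
    return set(edges)


def linearize(graph: AdjacencyGraph, min_weight: int = 1) -> list[AncestralContig]:
    """Linearize the adjacency graph into ancestral contigs.

    Edges below ``min_weight`` are dropped; within each connected component a
    maximum-weight linear subgraph is selected (exactly for components of up
    to EXACT_MAX_NODES nodes, greedily by descending weight beyond that); its
    paths are the ancestral contigs, sorted by decreasing length (ties by
    smallest HOG id).  A contig arising from a pure cycle component
    (plasmid-like) is flagged circular; the lost adjacency is the one the
    optimizer drops.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.graph.nodes)
    for u, v, w in graph.graph.edges(data="weight"):
        if w >= min_weight:
            g.add_edge(u, v, weight=w)

    accepted: set[frozenset] = set()
    circular_nodes: set[str] = set()
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) >= 3 and all(d == 2 for _, d in sub.degree()):
            circular_nodes.update(comp)
        if len(comp) <= EXACT_MAX_NODES:
            accepted |= max_weight_linear_forest(sub)
        else:
            accepted |= _greedy_linear_forest(sub)

    path_graph = nx.Graph()
    path_graph.add_nodes_from(g.nodes)
    path_graph.add_edges_from(tuple(e) for e in accepted)
    contigs: list[AncestralContig] = []
    for comp in nx.connected_components(path_graph):
        if len(comp) == 1:
            (node,) = comp
            contigs.append(AncestralContig([node], was_circular=node in circular_nodes))
            continue
        sub = path_graph.subgraph(comp)
        ends = sorted(n for n, d in sub.degree() if d == 1)
        start = ends[0]
        order = [start]
        prev = None
        while True:
            nxt = [n for n in sub.neighbors(order[-1]) if n != prev]
            if not nxt:
                break
            prev = order[-1]
            order.append(nxt[0])
        contigs.append(
            AncestralContig(order, was_circular=all(n in circular_nodes for n in comp))
        )
    contigs.sort(key=lambda c: (-c.length, min(c.hog_ids)))
    return contigs


def ancestral_contigs(
    genomes: list[ExtantGenome],
    forest: HOGForest,
    tree: SpeciesTree,
    level: str,
    min_weight: int = 1,
) -> tuple[list[AncestralContig], AdjacencyGraph]:
    """Full pipeline at one level: project, count adjacencies, linearize."""
    level_genes = hogs_at_level(forest, tree, level)
    projected = project_genomes(genomes, forest, tree, level, level_genes)
    graph = build_adjacency_graph(projected, level, level_genes)
    return linearize(graph, min_weight), graph


# ---------------------------------------------------------------------------
# Local synteny viewer


@dataclass
class SyntenyEntry:
    id: str
    color_class: str | None  # the reference-level HOG this entry descends from
    is_focal: bool = False


@dataclass
class SyntenyRow:
    taxon: str
    kind: str  # "ancestral" or "extant"
    entries: list[SyntenyEntry]


@dataclass
class SyntenyView:
    focal: str
    level: str
    rows: list[SyntenyRow]
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "level": self.level,
            "warning": self.warning,
            "rows": [
                {
                    "taxon": r.taxon,
                    "kind": r.kind,
                    "entries": [
                        {"id": e.id, "color_class": e.color_class, "is_focal": e.is_focal}
                        for e in r.entries
                    ],
                }
                for r in self.rows
            ],
        }


def _contig_slice(sequence: list[str], pos: int, window: int) -> list[str]:
    return sequence[max(0, pos - window) : pos + window + 1]


def synteny_window(
    focal: str,
    level: str,
    forest: HOGForest,
    tree: SpeciesTree,
    genomes: list[ExtantGenome],
    window: int = DEFAULT_WINDOW,
    collapsed: set[str] | frozenset[str] = frozenset(),
    min_weight: int = 1,
) -> SyntenyView:
    """Phylogeny-aware neighborhood of a focal HOG (or extant gene).

    The top row shows the focal ancestral gene with up to ``window`` inferred
    flanking HOGs in both directions.  Below, one row per extant genome of
    the clade (or per collapsed internal node, shown as the neighborhood of
    the corresponding ancestral gene).  Entries are colored by the
    reference-level HOG their own family maps to; entries with no homology to
    the reference level are grey (color_class None).
    """
    level_genes = hogs_at_level(forest, tree, level)
    gene2hog = gene_to_hog_map(level_genes)
    by_id = {ag.hog_id: ag for ag in level_genes}

    if focal in by_id:
        focal_hog = focal
    elif focal in gene2hog:
        focal_hog = gene2hog[focal]
    else:
        raise ValidationError(f"focal {focal!r} is neither a HOG at {level} nor a member gene")
    focal_ag = by_id[focal_hog]

    # map any HOG node at a deeper level back to its reference-level HOG
    level_node_ids = {id(ag.node): ag.hog_id for ag in level_genes}

    def level_class_of(node: HOGNode | None) -> str | None:
        while node is not None:
            hit = level_node_ids.get(id(node))
            if hit is not None:
                return hit
            node = node.parent
        return None

    contigs, _graph = ancestral_contigs(genomes, forest, tree, level, min_weight)
    warning = None
    top_entries: list[SyntenyEntry] = []
    placed = False
    for contig in contigs:
        if focal_hog in contig.hog_ids:
            pos = contig.hog_ids.index(focal_hog)
            for h in _contig_slice(contig.hog_ids, pos, window):
                top_entries.append(SyntenyEntry(h, h, is_focal=h == focal_hog))
            placed = True
            break
    if not placed:
        warning = "focal HOG lies on no ancestral contig; showing it alone"
        top_entries = [SyntenyEntry(focal_hog, focal_hog, is_focal=True)]
    rows = [SyntenyRow(level, "ancestral", top_entries)]

    genome_by_species = {g.species: g for g in genomes}
    focal_members = set(g for g, _ in focal_ag.members)

    def emit_extant(species: str) -> None:
        genome = genome_by_species.get(species)
        if genome is None:
            return
        for contig in sorted(genome.contigs):
            for rec in genome.contigs[contig]:
                if rec.gene_id not in focal_members:
                    continue
                seq = genome.contigs[contig]
                entries = []
                for neighbor in _contig_slice([r.gene_id for r in seq], rec.rank, window):
                    entries.append(
                        SyntenyEntry(
                            neighbor,
                            gene2hog.get(neighbor),
                            is_focal=neighbor == rec.gene_id,
                        )
                    )
                rows.append(SyntenyRow(species, "extant", entries))

    def emit_collapsed(taxon: str) -> None:
        sub_genes = hogs_at_level(forest, tree, taxon)
        descendants = [ag for ag in sub_genes if level_class_of(ag.node) == focal_hog]
        if not descendants:
            return
        sub_contigs, _ = ancestral_contigs(genomes, forest, tree, taxon, min_weight)
        sub_by_id = {ag.hog_id: ag for ag in sub_genes}
        for ag in descendants:
            entries = None
            for contig in sub_contigs:
                if ag.hog_id in contig.hog_ids:
                    pos = contig.hog_ids.index(ag.hog_id)
                    entries = [
                        SyntenyEntry(
                            h,
                            level_class_of(sub_by_id[h].node) if h in sub_by_id else None,
                            is_focal=h == ag.hog_id,
                        )
                        for h in _contig_slice(contig.hog_ids, pos, window)
                    ]
                    break
            if entries is None:
                entries = [SyntenyEntry(ag.hog_id, focal_hog, is_focal=True)]
            rows.append(SyntenyRow(taxon, "ancestral", entries))

    def descend(taxon: str) -> None:
        node = tree.node(taxon)
        if taxon in collapsed and not node.is_leaf:
            emit_collapsed(taxon)
            return
        if node.is_leaf:
            emit_extant(taxon)
            return
        for child in node.children:
            descend(child.name)

    for child in tree.node(level).children:
        descend(child.name)
    return SyntenyView(focal=focal_hog, level=level, rows=rows, warning=warning)
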