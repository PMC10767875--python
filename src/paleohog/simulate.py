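"""Synthetic clades with planted ground truth.

A root genome of ordered genes evolves down a species tree; along each branch
duplications (copy inserted adjacent to its template), gains (new family at a
uniform position), losses (deletions) and inversions (reversal of a uniform
interval) are applied in that order, with event counts drawn Poisson at the
configured per-branch expectations.  The simulator emits exactly the four
inputs the toolkit parses -- Newick, OrthoXML with true group structure and
true taxonomic ranges, per-genome gene-order TSV, OBO + GAF -- together with
the planted truth: per-ancestor gene content, gene order, per-branch events
and ancestral term sets, all restricted to what the emitted extant data can
witness (lineages that left no extant descendant are pruned everywhere, so
the ground truth stays consistent with the files by construction).
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict

from .formats_io import assign_hog_ids, serialize_hogs, serialize_species_tree
from .model import (
    LEAF_GENE,
    ORTHOLOG,
    PARALOG,
    HOGForest,
    HOGNode,
    SpeciesTree,
    TaxonNode,
    ValidationError,
)

GO_ROOTS = {
    "biological_process": "GO:0008150",
    "molecular_function": "GO:0003674",
    "cellular_component": "GO:0005575",
}
_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic clade."""

    n_species: int = 8
    tree_shape: str = "balanced"  # balanced | caterpillar | random
    n_ancestral_genes: int = 100
    gain_rate: float = 2.0  # expected gains per branch
    loss_rate: float = 2.0  # expected losses per branch
    duplication_rate: float = 1.0  # expected duplications per branch
    n_inversions: int = 1  # inversions per branch (fixed count)
    ontology_size: int = 60  # total terms across the three namespaces
    terms_per_gene: int = 2
    annotation_noise: float = 0.05  # fraction of extant genes with one spurious term
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted truth, pruned to extant-witnessable lineages."""

    content: dict[str, list[str]]  # internal node -> HOG ids
    order: dict[str, list[list[str]]]  # internal node -> contigs of HOG ids
    events: dict[str, dict[str, list[str]]]  # internal node -> event -> HOG ids
    terms: dict[str, dict[str, list[str]]]  # internal node -> HOG id -> terms
    family_terms: dict[str, list[str]]  # root HOG id -> planted terms
    n_planted_duplications: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SimulationOutput:
    newick: str
    orthoxml: str
    gene_orders_tsv: str
    obo: str
    gaf: str
    ground_truth: GroundTruth
    config: SimulationConfig
    warnings: list[str] = field(default_factory=list)


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


# ---------------------------------------------------------------------------
# Species tree shapes


def _make_tree(config: SimulationConfig, rng: random.Random) -> SpeciesTree:
    n = config.n_species
    if n < 2:
        raise ValidationError("a clade needs at least 2 species")
    leaves = [TaxonNode(f"S{i + 1:02d}") for i in range(n)]

    def join(a: TaxonNode, b: TaxonNode) -> TaxonNode:
        node = TaxonNode("")
        node.children = [a, b]
        a.parent = b.parent = node
        return node

    if config.tree_shape == "balanced":
        level = leaves
        while len(level) > 1:
            nxt = []
            for i in range(0, len(level) - 1, 2):
                nxt.append(join(level[i], level[i + 1]))
            if len(level) % 2:
                nxt.append(level[-1])
            level = nxt
        root = level[0]
    elif config.tree_shape == "caterpillar":
        root = leaves[0]
        for leaf in leaves[1:]:
            root = join(root, leaf)
    elif config.tree_shape == "random":
        pool = list(leaves)
        while len(pool) > 1:
            i = rng.randrange(len(pool))
            a = pool.pop(i)
            j = rng.randrange(len(pool))
            b = pool.pop(j)
            pool.append(join(a, b))
        root = pool[0]
    else:
        raise ValidationError(f"unknown tree shape: {config.tree_shape!r}")

    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            counter += 1
            node.name = f"N{counter}"
        stack.extend(reversed(node.children))
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# Simulation


def simulate(config: SimulationConfig) -> SimulationOutput:
    rng = random.Random(config.seed)
    tree = _make_tree(config, rng)
    warnings: list[str] = []
    depth = max(
        sum(1 for _ in _path_to_root(tree, leaf)) for leaf in tree.leaf_names
    )
    if config.loss_rate * depth >= config.n_ancestral_genes:
        warnings.append(
            "expected losses over the tree depth reach the root genome size; "
            "genomes may go extinct"
        )

    # --- evolve copies -----------------------------------------------------
    next_uid = 0
    copy_family: dict[int, int] = {}
    copy_parent: dict[int, int | None] = {}
    children_at: dict[tuple[int, str], list[int]] = {}
    contents: dict[str, list[int]] = {}
    origin: dict[int, str] = {}
    next_family = 0

    def new_copy(fam: int, parent: int | None) -> int:
        nonlocal next_uid
        uid = next_uid
        next_uid += 1
        copy_family[uid] = fam
        copy_parent[uid] = parent
        return uid

    root_name = tree.root.name
    genome0 = []
    for _ in range(config.n_ancestral_genes):
        fam = next_family
        next_family += 1
        origin[fam] = root_name
        genome0.append(new_copy(fam, None))
    contents[root_name] = genome0

    def evolve(node: TaxonNode) -> None:
        nonlocal next_family
        for child in node.children:
            genome = []
            for u in contents[node.name]:
                v = new_copy(copy_family[u], u)
                children_at.setdefault((u, child.name), []).append(v)
                genome.append(v)
            # duplications: copy inserted adjacent to its template
            for _ in range(_poisson(rng, config.duplication_rate)):
                if not genome:
                    break
                i = rng.randrange(len(genome))
                template = genome[i]
                w = new_copy(copy_family[template], copy_parent[template])
                if copy_parent[template] is not None:
                    children_at[(copy_parent[template], child.name)].append(w)
                genome.insert(i + 1, w)
            # gains: new family at a uniform position
            for _ in range(_poisson(rng, config.gain_rate)):
                fam = next_family
                next_family += 1
                origin[fam] = child.name
                genome.insert(rng.randrange(len(genome) + 1), new_copy(fam, None))
            # losses
            for _ in range(min(_poisson(rng, config.loss_rate), len(genome))):
                lost = genome.pop(rng.randrange(len(genome)))
                if copy_parent[lost] is not None:
                    children_at[(copy_parent[lost], child.name)].remove(lost)
            # inversions
            for _ in range(config.n_inversions):
                if len(genome) >= 2:
                    i = rng.randrange(len(genome))
                    j = rng.randrange(len(genome))
                    i, j = min(i, j), max(i, j)
                    genome[i : j + 1] = genome[i : j + 1][::-1]
            contents[child.name] = genome
            evolve(child)

    evolve(tree.root)

    # --- prune to lineages with extant evidence ----------------------------
    evidence: dict[int, bool] = {}

    def mark(node: TaxonNode) -> None:
        for child in node.children:
            mark(child)
        for u in contents[node.name]:
            if node.is_leaf:
                evidence[u] = True
            else:
                evidence[u] = any(
                    evidence.get(k, False)
                    for child in node.children
                    for k in children_at.get((u, child.name), [])
                )

    mark(tree.root)

    # --- extant gene ids and gene orders -----------------------------------
    gene_ids: dict[int, str] = {}
    order_lines = ["# species\tcontig\tstart\tgene_id"]
    for leaf in sorted(tree.leaf_names):
        for pos, u in enumerate(contents[leaf]):
            gid = f"{leaf}_{pos + 1:05d}"
            gene_ids[u] = gid
            order_lines.append(f"{leaf}\tc0\t{pos * 100}\t{gid}")
    gene_orders_tsv = "\n".join(order_lines) + "\n"

    # --- true HOG forest ----------------------------------------------------
    # a family may own several origin-less copies when a fresh gain is
    # duplicated on the branch it arose; those share the origin node
    origin_copies: dict[int, list[int]] = {}
    for name in [n.name for n in tree.preorder()]:
        for u in contents[name]:
            if copy_parent[u] is None:
                origin_copies.setdefault(copy_family[u], []).append(u)

    copy_hog: dict[int, HOGNode] = {}

    def build_node(u: int, node_name: str) -> HOGNode:
        node = tree.node(node_name)
        if node.is_leaf:
            leaf = HOGNode(LEAF_GENE, gene_id=gene_ids[u], species=node_name)
            copy_hog[u] = leaf
            return leaf
        hog = HOGNode(ORTHOLOG, level=node_name)
        copy_hog[u] = hog
        for child in node.children:
            kids = [k for k in children_at.get((u, child.name), []) if evidence.get(k)]
            if not kids:
                continue
            if len(kids) == 1:
                hog.add_child(build_node(kids[0], child.name))
            else:
                par = HOGNode(PARALOG, level=node_name)
                for k in kids:
                    par.add_child(build_node(k, child.name))
                hog.add_child(par)
        return hog

    roots: list[HOGNode] = []
    n_planted_dups = 0
    for fam in sorted(origin_copies):
        orig = origin[fam]
        if tree.node(orig).is_leaf:
            continue  # terminal-branch gain: a singleton, witnessed by no ancestor
        for u in origin_copies[fam]:
            if not evidence.get(u):
                continue
            root_node = build_node(u, orig)
            assign_hog_ids(root_node, f"HOG:{fam + 1:07d}")
            roots.append(root_node)
    forest = HOGForest(roots)
    for r in roots:
        for n in r.iter_nodes():
            if n.kind == PARALOG:
                n_planted_dups += 1

    orthoxml = serialize_hogs(forest, tree)

    # --- ground truth: content, order, events ------------------------------
    def hog_id_of(u: int) -> str | None:
        node = copy_hog.get(u)
        return node.hog_id if node is not None else None

    content: dict[str, list[str]] = {}
    order: dict[str, list[list[str]]] = {}
    for name in tree.internal_names():
        ids = [hog_id_of(u) for u in contents[name] if evidence.get(u) and u in copy_hog]
        ids = [h for h in ids if h is not None]
        content[name] = sorted(ids)
        order[name] = [ids] if ids else []

    events: dict[str, dict[str, list[str]]] = {}
    for name in tree.internal_names():
        node = tree.node(name)
        if node.parent is None:
            continue
        parent_name = node.parent.name
        ev = {"gained": [], "retained": [], "duplicated": [], "lost": []}
        for u in contents[parent_name]:
            if not (evidence.get(u) and u in copy_hog):
                continue
            kids = [
                k
                for k in children_at.get((u, name), [])
                if evidence.get(k) and k in copy_hog
            ]
            if not kids:
                ev["lost"].append(hog_id_of(u))
            elif len(kids) == 1:
                ev["retained"].append(hog_id_of(kids[0]))
            else:
                ev["duplicated"].extend(hog_id_of(k) for k in kids)
        for u in contents[name]:
            if copy_parent[u] is None and evidence.get(u) and u in copy_hog:
                ev["gained"].append(hog_id_of(u))
        events[name] = {k: sorted(v) for k, v in ev.items()}

    # --- ontology and annotations ------------------------------------------
    obo, leaf_terms, term_ns = _make_ontology(config, rng)
    family_terms: dict[int, list[str]] = {}
    for fam in sorted(origin_copies):
        k = min(config.terms_per_gene, len(leaf_terms))
        family_terms[fam] = sorted(rng.sample(leaf_terms, k))

    gaf_lines = ["!gaf-version: 2.2"]
    gaf_rows: list[tuple[str, str]] = []
    for leaf in sorted(tree.leaf_names):
        for u in contents[leaf]:
            gid = gene_ids[u]
            terms = list(family_terms[copy_family[u]])
            if rng.random() < config.annotation_noise:
                terms.append(rng.choice(leaf_terms))
            for t in sorted(set(terms)):
                gaf_rows.append((gid, t))
    for gid, t in gaf_rows:
        aspect = _ASPECT[term_ns[t]]
        gaf_lines.append(
            "\t".join(
                [
                    "paleohog", gid, gid, "", t, "PH:0000001", "IEA", "",
                    aspect, "", "", "protein", "taxon:0", "20240101",
                    "paleohog", "", "",
                ]
            )
        )
    gaf = "\n".join(gaf_lines) + "\n"

    truth_terms: dict[str, dict[str, list[str]]] = {}
    for name in tree.internal_names():
        per_hog: dict[str, list[str]] = {}
        for u in contents[name]:
            if evidence.get(u) and u in copy_hog:
                per_hog[hog_id_of(u)] = family_terms[copy_family[u]]
        truth_terms[name] = per_hog

    truth = GroundTruth(
        content=content,
        order=order,
        events=events,
        terms=truth_terms,
        family_terms={
            f"HOG:{fam + 1:07d}": terms for fam, terms in family_terms.items()
            if not tree.node(origin[fam]).is_leaf
        },
        n_planted_duplications=n_planted_dups,
    )
    return SimulationOutput(
        newick=serialize_species_tree(tree),
        orthoxml=orthoxml,
        gene_orders_tsv=gene_orders_tsv,
        obo=obo,
        gaf=gaf,
        ground_truth=truth,
        config=config,
        warnings=warnings,
    )


def _path_to_root(tree: SpeciesTree, name: str):
    node = tree.node(name)
    while node.parent is not None:
        yield node
        node = node.parent


# ---------------------------------------------------------------------------
# Synthetic ontology


def _make_ontology(
    config: SimulationConfig, rng: random.Random
) -> tuple[str, list[str], dict[str, str]]:
    """A layered random DAG under the three GO namespace roots.

    Upper-layer terms hang off the root by is_a; leaf-layer terms get one
    is_a parent in the upper layer and occasionally a second part_of parent.
    Returns the OBO text, the leaf (assignable) term ids, and the
    term -> namespace map.
    """
    term_ns: dict[str, str] = {}
    stanzas = ["format-version: 1.2", "ontology: paleohog-synthetic"]
    leaf_terms: list[str] = []
    next_id = 100001
    per_ns = max(3, config.ontology_size // 3)
    for ns in ("biological_process", "molecular_function", "cellular_component"):
        root = GO_ROOTS[ns]
        term_ns[root] = ns
        stanzas += ["", "[Term]", f"id: {root}", f"name: {ns}", f"namespace: {ns}"]
        n_upper = max(1, per_ns // 3)
        upper: list[str] = []
        for _ in range(n_upper):
            tid = f"GO:{next_id:07d}"
            next_id += 1
            term_ns[tid] = ns
            upper.append(tid)
            stanzas += [
                "", "[Term]", f"id: {tid}", f"name: synthetic {ns} branch {tid[-4:]}",
                f"namespace: {ns}", f"is_a: {root} ! {ns}",
            ]
        for _ in range(per_ns - n_upper):
            tid = f"GO:{next_id:07d}"
            next_id += 1
            term_ns[tid] = ns
            leaf_terms.append(tid)
            parent = rng.choice(upper)
            lines = [
                "", "[Term]", f"id: {tid}", f"name: synthetic {ns} term {tid[-4:]}",
                f"namespace: {ns}", f"is_a: {parent} ! branch",
            ]
            others = [u for u in upper if u != parent]
            if others and rng.random() < 0.3:
                lines.append(f"relationship: part_of {rng.choice(others)} ! branch")
            stanzas += lines
    stanzas += [
        "", "[Typedef]", "id: part_of", "name: part of",
        "xref: BFO:0000050", "is_transitive: true",
    ]
    return "\n".join(stanzas) + "\n", leaf_terms, term_ns
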