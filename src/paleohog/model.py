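"""Core in-memory containers: species tree, extant genomes, HOG forest, ontology.

Coordinates are 0-based half-open internally.  Strand is recorded for display
but never used in downstream computation (adjacencies are unordered).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator


class ValidationError(ValueError):
    """Input violates a structural invariant of the data model."""


class NewickParseError(ValueError):
    """Malformed Newick input."""


# ---------------------------------------------------------------------------
# Species tree


class TaxonNode:
    """One node of the species tree: an extant species (leaf) or taxonomic level."""

    __slots__ = ("name", "parent", "children")

    def __init__(self, name: str, parent: "TaxonNode | None" = None):
        self.name = name
        self.parent = parent
        self.children: list[TaxonNode] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"TaxonNode({self.name!r})"


class SpeciesTree:
    """Rooted species tree with uniquely labeled nodes.

    Leaves are extant species; internal nodes are the taxonomic levels at
    which ancestral genomes are reconstructed.
    """

    def __init__(self, root: TaxonNode):
        self.root = root
        self.nodes: dict[str, TaxonNode] = {}
        for node in self.preorder():
            if node.name in self.nodes:
                raise ValidationError(f"duplicate taxon label: {node.name!r}")
            self.nodes[node.name] = node
        self._clade_cache: dict[str, frozenset[str]] = {}
        self._depth: dict[str, int] = {}
        for node in self.preorder():
            self._depth[node.name] = (
                0 if node.parent is None else self._depth[node.parent.name] + 1
            )

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[TaxonNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TaxonNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_names(self) -> list[str]:
        return [n.name for n in self.preorder() if not n.is_leaf]

    # -- queries ------------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def node(self, name: str) -> TaxonNode:
        try:
            return self.nodes[name]
        except KeyError:
            raise ValidationError(f"unknown taxon: {name!r}") from None

    def clade_leaves(self, name: str) -> frozenset[str]:
        """Leaf species names under (and including) the named node."""
        cached = self._clade_cache.get(name)
        if cached is not None:
            return cached
        node = self.node(name)
        if node.is_leaf:
            result = frozenset([name])
        else:
            acc: set[str] = set()
            stack = [node]
            while stack:
                n = stack.pop()
                if n.is_leaf:
                    acc.add(n.name)
                else:
                    stack.extend(n.children)
            result = frozenset(acc)
        self._clade_cache[name] = result
        return result

    def is_ancestor_or_equal(self, anc: str, desc: str) -> bool:
        """True if `anc` lies on the root path of `desc` (or equals it)."""
        node = self.node(desc)
        target = self.node(anc)
        while node is not None:
            if node is target:
                return True
            node = node.parent
        return False

    def lca(self, names: Iterable[str]) -> str:
        """Label of the last common ancestor of the named taxa."""
        names = list(names)
        if not names:
            raise ValidationError("lca of an empty taxon set")
        paths = []
        for name in names:
            node = self.node(name)
            path = []
            while node is not None:
                path.append(node.name)
                node = node.parent
            paths.append(path[::-1])
        lca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            label = paths[0][depth]
            if all(p[depth] == label for p in paths):
                lca = label
            else:
                break
        return lca

    def parent_of(self, name: str) -> str | None:
        p = self.node(name).parent
        return p.name if p is not None else None


# ---------------------------------------------------------------------------
# Extant genomes


@dataclass(frozen=True)
class GeneRecord:
    """An extant gene anchored on a contig.  `start` is 0-based half-open."""

    gene_id: str
    species: str
    contig: str
    start: int
    rank: int = 0
    strand: str = "."


class ExtantGenome:
    """Ordered gene lists per contig for one extant species."""

    def __init__(self, species: str, contigs: dict[str, list[GeneRecord]]):
        self.species = species
        self.contigs: dict[str, list[GeneRecord]] = {}
        seen: set[str] = set()
        for contig, genes in contigs.items():
            ordered = sorted(genes, key=lambda g: (g.start, g.gene_id))
            ranked = [
                GeneRecord(g.gene_id, g.species, g.contig, g.start, rank, g.strand)
                for rank, g in enumerate(ordered)
            ]
            for g in ranked:
                if g.gene_id in seen:
                    raise ValidationError(
                        f"duplicate gene_id {g.gene_id!r} in species {species!r}"
                    )
                seen.add(g.gene_id)
            self.contigs[contig] = ranked

    def genes(self) -> Iterator[GeneRecord]:
        for contig in self.contigs.values():
            yield from contig

    def n_genes(self) -> int:
        return sum(len(c) for c in self.contigs.values())


# ---------------------------------------------------------------------------
# HOG forest

ORTHOLOG = "ortholog-group"
PARALOG = "paralog-group"
LEAF_GENE = "leaf-gene"


class HOGNode:
    """A node of one gene family's hierarchical group tree.

    Ortholog-group nodes carry a taxonomic level and a HOG identifier; a
    paralog-group node marks a duplication whose children are the diverged
    copies; leaf-gene nodes are extant genes.
    """

    __slots__ = ("kind", "hog_id", "level", "children", "parent", "gene_id", "species")

    def __init__(
        self,
        kind: str,
        hog_id: str | None = None,
        level: str | None = None,
        gene_id: str | None = None,
        species: str | None = None,
    ):
        self.kind = kind
        self.hog_id = hog_id
        self.level = level
        self.gene_id = gene_id
        self.species = species
        self.children: list[HOGNode] = []
        self.parent: HOGNode | None = None

    def add_child(self, child: "HOGNode") -> None:
        child.parent = self
        self.children.append(child)

    def iter_nodes(self) -> Iterator["HOGNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def members(self) -> list[tuple[str, str]]:
        """All (gene_id, species) pairs of extant genes under this node."""
        out = []
        for node in self.iter_nodes():
            if node.kind == LEAF_GENE:
                out.append((node.gene_id, node.species))
        return out

    def member_species(self) -> set[str]:
        return {sp for _, sp in self.members()}

    def __repr__(self) -> str:  # pragma: no cover
        if self.kind == LEAF_GENE:
            return f"HOGNode(gene={self.gene_id})"
        return f"HOGNode({self.kind}, id={self.hog_id}, level={self.level})"


class HOGForest:
    """All gene family trees plus lookup indices."""

    def __init__(self, roots: list[HOGNode]):
        self.roots = roots
        self.gene_index: dict[str, HOGNode] = {}
        for root in roots:
            for node in root.iter_nodes():
                if node.kind == LEAF_GENE:
                    if node.gene_id in self.gene_index:
                        raise ValidationError(
                            f"gene {node.gene_id!r} appears in more than one family"
                        )
                    self.gene_index[node.gene_id] = node

    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def level_index(self) -> dict[tuple[str, str], HOGNode]:
        """(level, hog_id) -> deepest ortholog-group node with that id at that level."""
        idx: dict[tuple[str, str], HOGNode] = {}
        for root in self.roots:
            for node in root.iter_nodes():
                if node.kind == ORTHOLOG and node.level is not None:
                    idx[(node.level, node.hog_id)] = node
        return idx


# ---------------------------------------------------------------------------
# Gene Ontology + annotations


@dataclass
class TermRecord:
    term_id: str
    name: str
    namespace: str
    parents: frozenset[str]
    obsolete: bool = False


class GeneOntology:
    """GO DAG restricted to is_a / part_of edges, with alt_id aliasing."""

    def __init__(self, terms: dict[str, TermRecord], alt_ids: dict[str, str] | None = None):
        self.terms = terms
        self.alt_ids = alt_ids or {}
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        roots: dict[str, str] = {}
        for t in terms.values():
            if not t.obsolete and not t.parents:
                roots.setdefault(t.namespace, t.term_id)
        self.namespace_roots = roots

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its primary id (identity for primary ids)."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise KeyError(f"unknown GO term: {term_id}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def term(self, term_id: str) -> TermRecord:
        return self.terms[self.resolve(term_id)]

    def namespace(self, term_id: str) -> str:
        return self.term(term_id).namespace

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All is_a/part_of ancestors of the term, excluding the term itself."""
        term_id = self.resolve(term_id)
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        acc: set[str] = set()
        stack = list(self.terms[term_id].parents)
        while stack:
            p = stack.pop()
            if p in acc or p not in self.terms:
                continue
            if self.terms[p].obsolete:
                continue
            acc.add(p)
            stack.extend(self.terms[p].parents)
        result = frozenset(acc)
        self._ancestor_cache[term_id] = result
        return result

    def is_ancestor(self, anc: str, desc: str) -> bool:
        return self.resolve(anc) in self.ancestors(desc)


@dataclass
class AnnotationRow:
    subject_id: str
    term_id: str
    evidence_code: str = ""


class AnnotationTable:
    """Non-redundant subject -> GO term assignments.

    Stored as the most specific terms necessary: no subject carries a term
    that is an ancestor of another of its terms.
    """

    def __init__(self, rows: Iterable[AnnotationRow], ontology: GeneOntology):
        by_subject: dict[str, dict[str, AnnotationRow]] = {}
        for row in rows:
            term = ontology.resolve(row.term_id)
            by_subject.setdefault(row.subject_id, {})[term] = AnnotationRow(
                row.subject_id, term, row.evidence_code
            )
        self.rows: list[AnnotationRow] = []
        for subject in sorted(by_subject):
            terms = by_subject[subject]
            redundant = set()
            for t in terms:
                redundant.update(ontology.ancestors(t) & terms.keys())
            for t in sorted(terms):
                if t not in redundant:
                    self.rows.append(terms[t])

    def subject_terms(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for row in self.rows:
            out.setdefault(row.subject_id, set()).add(row.term_id)
        return out

    def __len__(self) -> int:
        return len(self.rows)
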