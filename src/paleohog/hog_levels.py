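"""Ancestral genomes as level-specific HOG sets.

The HOGs defined at one internal node of the species tree are the proxies for
that ancestor's genes.  This module extracts them, scores their completeness
(fraction of the clade's species represented in the HOG, a quality proxy for
the inference), and classifies each gene's fate on the branch from the parent
level: retained in single copy, duplicated, gained, or (for parent-level genes
with no descendant) lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .model import LEAF_GENE, ORTHOLOG, PARALOG, HOGForest, HOGNode, SpeciesTree, ValidationError

DEFAULT_MIN_COMPLETENESS = 0.3

RETAINED = "retained"
DUPLICATED = "duplicated"
GAINED = "gained"
LOST = "lost"
EVENTS = (RETAINED, DUPLICATED, GAINED, LOST)


@dataclass
class AncestralGene:
    """One inferred gene of an ancestral genome: a HOG restricted to a level."""

    hog_id: str
    level: str
    root_hog_id: str
    members: list[tuple[str, str]]  # (gene_id, species), inside the clade only
    n_species_present: int
    completeness: Fraction
    event: str | None = None
    node: HOGNode | None = field(default=None, repr=False, compare=False)

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class AncestralGenome:
    level: str
    genes: list[AncestralGene]
    parent_level: str | None = None
    lost: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)


def _root_id(node: HOGNode) -> str:
    while node.parent is not None:
        node = node.parent
    return node.hog_id


def hogs_at_level(forest: HOGForest, tree: SpeciesTree, level: str) -> list[AncestralGene]:
    """All ancestral genes (level-specific HOGs) at one internal taxon.

    For each family, the deepest group nodes whose level is an ancestor of (or
    equal to) the query level and whose members intersect the query clade are
    returned, with membership restricted to the clade.  A duplication above
    the level therefore yields one ancestral gene per surviving copy.
    """
    node_t = tree.node(level)
    if node_t.is_leaf:
        raise ValidationError(
            f"{level!r} is an extant species; list its genes from the genome instead"
        )
    clade = tree.clade_leaves(level)
    n_clade = len(clade)
    out: list[AncestralGene] = []

    def clade_members(node: HOGNode) -> list[tuple[str, str]]:
        return [(g, sp) for g, sp in node.members() if sp in clade]

    def descendable(node: HOGNode) -> list[HOGNode]:
        """Children through which the query level is reachable."""
        found: list[HOGNode] = []
        for child in node.children:
            if child.kind == ORTHOLOG:
                if (
                    child.level is not None
                    and tree.is_ancestor_or_equal(child.level, level)
                    and clade_members(child)
                ):
                    found.append(child)
            elif child.kind == PARALOG:
                for copy in child.children:
                    if (
                        copy.kind == ORTHOLOG
                        and copy.level is not None
                        and tree.is_ancestor_or_equal(copy.level, level)
                        and clade_members(copy)
                    ):
                        found.append(copy)
        return found

    def collect(node: HOGNode) -> None:
        members = clade_members(node)
        if not members:
            return
        deeper = descendable(node)
        if deeper:
            for child in deeper:
                collect(child)
            return
        species = {sp for _, sp in members}
        out.append(
            AncestralGene(
                hog_id=node.hog_id,
                level=level,
                root_hog_id=_root_id(node),
                members=sorted(members),
                n_species_present=len(species),
                completeness=Fraction(len(species), n_clade),
                node=node,
            )
        )

    for root in forest.roots:
        if root.level is not None and tree.is_ancestor_or_equal(root.level, level):
            collect(root)
    out.sort(key=lambda g: g.hog_id)
    return out


def completeness_score(gene: AncestralGene, tree: SpeciesTree) -> Fraction:
    """Species in the HOG over species in the clade; exact rational in [0, 1]."""
    return Fraction(gene.n_species_present, len(tree.clade_leaves(gene.level)))


def filter_by_completeness(
    genes: list[AncestralGene], threshold: float = DEFAULT_MIN_COMPLETENESS
) -> list[AncestralGene]:
    return [g for g in genes if g.completeness >= threshold]


def classify_events(
    forest: HOGForest, tree: SpeciesTree, level: str, parent_level: str
) -> tuple[dict[str, str], list[str]]:
    """Per-gene fate on the branch parent_level -> level.

    Returns ``(events, lost)`` where ``events`` maps each level HOG id to
    retained / duplicated / gained and ``lost`` lists parent-level HOG ids
    with no descendant gene at the level and no extant member in its clade.
    A parent gene with exactly one surviving level descendant is retained;
    with two or more, all siblings are duplicated; a family whose topmost
    level lies on the branch (inclusive of the level) is gained.
    """
    if parent_level == level or not tree.is_ancestor_or_equal(parent_level, level):
        raise ValidationError(
            f"{parent_level!r} is not an ancestor of {level!r} in the species tree"
        )
    parent_genes = hogs_at_level(forest, tree, parent_level)
    level_genes = hogs_at_level(forest, tree, level)
    clade = tree.clade_leaves(level)

    parent_by_node = {id(g.node): g for g in parent_genes}
    hits: dict[str, list[AncestralGene]] = {g.hog_id: [] for g in parent_genes}
    events: dict[str, str] = {}
    for gene in level_genes:
        node = gene.node
        counterpart = None
        while node is not None:
            pg = parent_by_node.get(id(node))
            if pg is not None:
                counterpart = pg
                break
            node = node.parent
        if counterpart is None:
            events[gene.hog_id] = GAINED
        else:
            hits[counterpart.hog_id].append(gene)

    lost: list[str] = []
    for pg in parent_genes:
        descendants = hits[pg.hog_id]
        if len(descendants) == 1:
            events[descendants[0].hog_id] = RETAINED
        elif len(descendants) >= 2:
            for d in descendants:
                events[d.hog_id] = DUPLICATED
        else:
            if not any(sp in clade for _, sp in pg.node.members()):
                lost.append(pg.hog_id)
            # else: the clade members sit under this parent gene but yielded no
            # level gene -- cannot happen for a well-formed forest
    return events, sorted(lost)


def ancestral_genome(
    forest: HOGForest,
    tree: SpeciesTree,
    level: str,
    parent_level: str | None = None,
    min_completeness: float = 0.0,
) -> AncestralGenome:
    """Assemble the ancestral genome at a level, with events when a parent is given.

    When ``parent_level`` is None the closest ancestral node in the species
    tree is used (the most recent parental genome); for the root no events are
    computed.
    """
    if parent_level is None:
        parent_level = tree.parent_of(level)
    genes = hogs_at_level(forest, tree, level)
    lost: list[str] = []
    if parent_level is not None:
        events, lost = classify_events(forest, tree, level, parent_level)
        for g in genes:
            g.event = events.get(g.hog_id)
    genes = filter_by_completeness(genes, min_completeness) if min_completeness else genes
    return AncestralGenome(level=level, genes=genes, parent_level=parent_level, lost=lost)
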