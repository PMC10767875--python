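"""Parsimonious propagation of GO annotations from extant genes to HOGs.

A leaf gene's functional profile is the upward closure of its annotations
(the true-path rule: every term implies its is_a/part_of ancestors).  Moving
bottom-up through a family tree, an internal node's support for a term is the
fraction of its children that carry the term, children counted once each;
the node is annotated with the term when support reaches the threshold tau.
This child-fraction parsimony rule is a deliberately simple reading of
belief-propagation-style annotation transfer: a term shared by most diverged
copies of a family was most parsimoniously present in their ancestor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .model import (
    LEAF_GENE,
    ORTHOLOG,
    GeneOntology,
    HOGForest,
    HOGNode,
    ValidationError,
)

DEFAULT_TAU = 0.5


@dataclass(frozen=True)
class AncestralAnnotation:
    hog_id: str
    level: str
    term_id: str
    support: float


class AncestralAnnotationSet:
    """Propagated (hog, level) -> term assignments, stored minimally.

    Per subject only the most specific terms are kept: an ancestor term is
    redundant when some annotated descendant term has at least equal support.
    """

    def __init__(self, rows: list[AncestralAnnotation]):
        self.rows = rows
        self._by_subject: dict[tuple[str, str], dict[str, float]] = {}
        for row in rows:
            self._by_subject.setdefault((row.hog_id, row.level), {})[row.term_id] = row.support

    def terms_for(self, hog_id: str, level: str) -> dict[str, float]:
        return dict(self._by_subject.get((hog_id, level), {}))

    def subjects(self) -> list[tuple[str, str]]:
        return sorted(self._by_subject)

    def __len__(self) -> int:
        return len(self.rows)


def term_closure(terms: set[str] | frozenset[str], ontology: GeneOntology) -> set[str]:
    """The terms plus all their is_a/part_of ancestors (true-path rule)."""
    out: set[str] = set()
    for t in terms:
        primary = ontology.resolve(t)  # KeyError for unknown terms
        if ontology.terms[primary].obsolete:
            raise ValidationError(f"obsolete term in closure request: {t}")
        out.add(primary)
        out.update(ontology.ancestors(primary))
    return out


def propagate_to_hogs(
    annotations,
    forest: HOGForest,
    ontology: GeneOntology,
    tau: float = DEFAULT_TAU,
    weight_by_size: bool = False,
) -> AncestralAnnotationSet:
    """Annotate every internal HOG node from its extant members' GO terms.

    ``annotations`` is an AnnotationTable or any mapping gene_id -> set of
    term ids.  Support for a term at a node is the (optionally member-count
    weighted) fraction of children whose propagated profile contains the
    term; profiles are closure-closed by construction, so support can only
    grow toward more general terms.  Emitted rows keep, per (hog_id, level),
    the most specific terms: an ancestor term appears only when its support
    strictly exceeds that of every annotated descendant.
    """
    if hasattr(annotations, "subject_terms"):
        gene_terms = annotations.subject_terms()
    else:
        gene_terms = {k: set(v) for k, v in annotations.items()}

    rows: list[AncestralAnnotation] = []

    def profile(node: HOGNode) -> dict[str, Fraction]:
        """term -> support among this node's children (leaves: closure, support 1)."""
        if node.kind == LEAF_GENE:
            terms = gene_terms.get(node.gene_id, set())
            return {t: Fraction(1) for t in term_closure(terms, ontology)}
        child_profiles = [profile(c) for c in node.children]
        if weight_by_size:
            weights = [max(1, len(c.members())) for c in node.children]
        else:
            weights = [1] * len(node.children)
        total = sum(weights)
        support: dict[str, Fraction] = {}
        for prof, w in zip(child_profiles, weights):
            for t in prof:
                support[t] = support.get(t, Fraction(0)) + Fraction(w, total)
        present = {t: s for t, s in support.items() if s >= tau}
        if node.kind == ORTHOLOG and node.level is not None and present:
            kept = _minimal_terms(present, ontology)
            for t in sorted(kept):
                rows.append(
                    AncestralAnnotation(node.hog_id, node.level, t, float(present[t]))
                )
        return present

    for root in forest.roots:
        profile(root)
    rows.sort(key=lambda r: (r.hog_id, r.level, r.term_id))
    return AncestralAnnotationSet(rows)


def _minimal_terms(support: dict[str, Fraction], ontology: GeneOntology) -> set[str]:
    """Drop every term that is an ancestor of another term with >= support."""
    kept = set(support)
    for t in support:
        for anc in ontology.ancestors(t):
            if anc in support and support[anc] <= support[t]:
                kept.discard(anc)
    return kept


# ---------------------------------------------------------------------------
# Term statistics over an annotation corpus


@dataclass(frozen=True)
class TermStat:
    count: int
    probability: Fraction
    information_content: float


class TermStats:
    """Per-term annotation frequency and information content over a corpus.

    count(t) is the number of subjects whose closure contains t; p(t) is
    count(t) over the count of t's namespace root (which is 1 by closure for
    every annotated subject of that namespace); IC(t) = -ln p(t).
    """

    def __init__(self, stats: dict[str, TermStat], ontology: GeneOntology):
        self.stats = stats
        self.ontology = ontology

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.stats

    def count(self, term_id: str) -> int:
        return self.stats[term_id].count

    def probability(self, term_id: str) -> Fraction:
        return self.stats[term_id].probability

    def information_content(self, term_id: str) -> float:
        return self.stats[term_id].information_content


def term_stats(corpus, ontology: GeneOntology) -> TermStats:
    """Compute TermStats from a corpus: a mapping subject -> set of terms
    (closure applied here) or an AnnotationTable."""
    if hasattr(corpus, "subject_terms"):
        corpus = corpus.subject_terms()
    if not corpus:
        raise ValidationError("term statistics over an empty corpus")
    counts: dict[str, int] = {}
    for terms in corpus.values():
        for t in term_closure(set(terms), ontology):
            counts[t] = counts.get(t, 0) + 1
    root_counts = {
        ns: counts.get(root, 0) for ns, root in ontology.namespace_roots.items()
    }
    stats: dict[str, TermStat] = {}
    for t, c in counts.items():
        ns = ontology.namespace(t)
        root_n = root_counts.get(ns, 0)
        if root_n == 0:
            continue
        p = Fraction(c, root_n)
        stats[t] = TermStat(c, p, -math.log(p))
    return TermStats(stats, ontology)


# ---------------------------------------------------------------------------
# Coverage accounting (annotated fraction of each ancestral genome)


@dataclass(frozen=True)
class CoverageRow:
    level: str
    n_annotated: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_annotated / self.n_total if self.n_total else 0.0


def annotation_coverage(
    annset: AncestralAnnotationSet, forest: HOGForest, tree, levels: list[str] | None = None
) -> list[CoverageRow]:
    """Per level: how many ancestral genes carry at least one propagated term."""
    from .hog_levels import hogs_at_level

    if levels is None:
        levels = tree.internal_names()
    annotated = {(h, lvl) for (h, lvl) in annset._by_subject}
    out = []
    for level in levels:
        genes = hogs_at_level(forest, tree, level)
        # an ancestral gene at `level` may be carried by a node annotated at
        # its own (possibly older) level when no divergence splits the branch
        n_ann = sum(1 for g in genes if (g.hog_id, g.node.level) in annotated)
        out.append(CoverageRow(level, n_ann, len(genes)))
    return out


def hog_annotations_at_level(
    annset: AncestralAnnotationSet, genes
) -> dict[str, set[str]]:
    """hog_id -> propagated term set for a list of AncestralGene at one level."""
    return {
        g.hog_id: set(annset.terms_for(g.hog_id, g.node.level)) for g in genes
    }
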