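"""GO over-representation analysis for extant genes or ancestral genes (HOGs).

For every term carried by at least one study subject (after closure), the
one-sided Fisher's exact test asks whether the study set is enriched for the
term relative to the population; p-values are corrected with Bonferroni or
Benjamini-Hochberg.  The population defaults to all genes of the study genome
(extant mode) or all HOGs at the stated taxonomic level (ancestral mode),
annotated or not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .go_propagation import term_closure
from .model import GeneOntology, ValidationError

DEFAULT_ALPHA = 0.05
DEFAULT_METHOD = "bh"

_NAMESPACE_SHORT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


def namespace_code(ontology: GeneOntology, term_id: str) -> str:
    ns = ontology.namespace(term_id)
    return _NAMESPACE_SHORT.get(ns, ns)


# ---------------------------------------------------------------------------
# Core statistics


def fisher_overrep(n_study: int, N_study: int, n_pop: int, N_pop: int) -> float:
    """One-sided (greater) Fisher's exact test for over-representation.

    Returns P[X >= n_study] for X ~ Hypergeometric(N_pop, n_pop, N_study):
    the chance that a uniform draw of N_study subjects from a population of
    N_pop containing n_pop annotated ones hits n_study or more of them.
    """
    if not (0 <= n_study <= min(N_study, n_pop)) or N_study > N_pop or n_pop > N_pop:
        raise ValidationError(
            f"inconsistent contingency counts: n_study={n_study}, N_study={N_study}, "
            f"n_pop={n_pop}, N_pop={N_pop}"
        )
    return float(hypergeom.sf(n_study - 1, N_pop, n_pop, N_study))


def correct_bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni family-wise correction: min(1, p * m)."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


def correct_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, reported in input order."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running = min(running, p[order[i]] * m / rank)
        adjusted[order[i]] = running
    return np.minimum(adjusted, 1.0)


# ---------------------------------------------------------------------------
# Input handling


def parse_id_list(text: str) -> tuple[set[str], int]:
    """Split identifiers on any mix of spaces, tabs, commas and newlines.

    Returns the identifier set and the number of duplicates dropped.
    """
    tokens = [t for t in re.split(r"[ \t,\r\n]+", text) if t]
    ids = set(tokens)
    return ids, len(tokens) - len(ids)


@dataclass
class EnrichmentInput:
    """A study set against a population, with closure-ready annotations."""

    mode: str  # "extant" | "ancestral"
    study: set[str]
    population: set[str]
    annotations: dict[str, set[str]]  # subject -> most specific terms
    level: str | None = None  # stated (ancestral) or inferred (extant) level

    def validate(self) -> None:
        if self.mode not in ("extant", "ancestral"):
            raise ValidationError(f"unknown enrichment mode: {self.mode!r}")
        stray = self.study - self.population
        if stray:
            raise ValidationError(
                f"study ids outside the population: {sorted(stray)[:10]}"
            )
        if self.mode == "ancestral" and self.level is None:
            raise ValidationError(
                "ancestral enrichment needs HOG ids from one stated taxonomic level"
            )


@dataclass
class EnrichmentRow:
    term_id: str
    name: str
    namespace: str
    p_uncorrected: float
    p_bonferroni: float
    p_bh: float
    n_study: int
    N_study: int
    n_pop: int
    N_pop: int
    study_hits: list[str] = field(default_factory=list)

    @property
    def ratio_study(self) -> float:
        return self.n_study / self.N_study

    @property
    def ratio_pop(self) -> float:
        return self.n_pop / self.N_pop

    @property
    def fold_change(self) -> float:
        return self.ratio_study / self.ratio_pop


@dataclass
class EnrichmentResult:
    rows: list[EnrichmentRow]  # significant rows, sorted by raw p
    all_rows: list[EnrichmentRow]  # every tested term
    m: int  # number of tested terms
    alpha: float
    method: str
    level: str | None = None


def run_enrichment(
    input: EnrichmentInput,
    ontology: GeneOntology,
    alpha: float = DEFAULT_ALPHA,
    method: str = DEFAULT_METHOD,
    test_universe: str = "study",
) -> EnrichmentResult:
    """Test every term present in the study closure (or, with
    ``test_universe='population'``, in the population closure) and report the
    terms whose corrected p-value is at most alpha, sorted by raw p-value.
    """
    input.validate()
    if method not in ("bh", "bonferroni"):
        raise ValidationError(f"unknown correction method: {method!r}")
    closures: dict[str, frozenset[str]] = {}
    for subject in input.population:
        terms = input.annotations.get(subject, set())
        closures[subject] = frozenset(term_closure(set(terms), ontology)) if terms else frozenset()

    pop_count: dict[str, int] = {}
    study_hits: dict[str, list[str]] = {}
    for subject in sorted(input.population):
        for t in closures[subject]:
            pop_count[t] = pop_count.get(t, 0) + 1
    for subject in sorted(input.study):
        for t in closures[subject]:
            study_hits.setdefault(t, []).append(subject)

    if test_universe == "study":
        universe = sorted(study_hits)
    elif test_universe == "population":
        universe = sorted(pop_count)
    else:
        raise ValidationError(f"unknown test universe: {test_universe!r}")

    N_study, N_pop = len(input.study), len(input.population)
    m = len(universe)
    raw = np.array(
        [
            fisher_overrep(len(study_hits.get(t, [])), N_study, pop_count[t], N_pop)
            for t in universe
        ]
    )
    bonf = correct_bonferroni(raw, m)
    bh = correct_bh(raw)

    all_rows = []
    for t, p, pb, ph in zip(universe, raw, bonf, bh):
        all_rows.append(
            EnrichmentRow(
                term_id=t,
                name=ontology.term(t).name,
                namespace=namespace_code(ontology, t),
                p_uncorrected=float(p),
                p_bonferroni=float(pb),
                p_bh=float(ph),
                n_study=len(study_hits.get(t, [])),
                N_study=N_study,
                n_pop=pop_count[t],
                N_pop=N_pop,
                study_hits=sorted(study_hits.get(t, [])),
            )
        )
    all_rows.sort(key=lambda r: (r.p_uncorrected, r.term_id))
    corrected = (lambda r: r.p_bh) if method == "bh" else (lambda r: r.p_bonferroni)
    significant = [r for r in all_rows if corrected(r) <= alpha]
    return EnrichmentResult(
        rows=significant, all_rows=all_rows, m=m, alpha=alpha, method=method,
        level=input.level,
    )


# ---------------------------------------------------------------------------
# Convenience constructors


def extant_input(
    study: set[str], genome, annotations: dict[str, set[str]], tree=None
) -> EnrichmentInput:
    """Study set of extant genes against all genes of their genome; when a
    species tree is given and the study spans several genomes, the implied
    taxonomic level (LCA of the study species) is recorded."""
    genomes = genome if isinstance(genome, list) else [genome]
    population = {g.gene_id for gm in genomes for g in gm.genes()}
    level = None
    if tree is not None:
        species = {gm.species for gm in genomes}
        level = tree.lca(species) if species else None
    return EnrichmentInput("extant", set(study), population, annotations, level)


def ancestral_input(
    study: set[str],
    level: str,
    forest,
    tree,
    annset,
    population: set[str] | None = None,
) -> EnrichmentInput:
    """Study set of HOG ids at one level against all HOGs at that level."""
    from .go_propagation import hog_annotations_at_level
    from .hog_levels import hogs_at_level

    genes = hogs_at_level(forest, tree, level)
    all_ids = {g.hog_id for g in genes}
    missing = sorted(set(study) - all_ids)
    if missing:
        raise ValidationError(
            f"study HOG ids not defined at level {level!r}: {missing[:10]} "
            "(HOG identifiers from one taxonomic level are required)"
        )
    annotations = hog_annotations_at_level(annset, genes)
    return EnrichmentInput(
        "ancestral", set(study), population or all_ids, annotations, level
    )


def study_from_events(
    forest, tree, level: str, parent_level: str, categories: set[str]
) -> set[str]:
    """Phylostratigraphy shortcut: the HOGs at `level` whose branch event
    (relative to `parent_level`) falls in the given categories; the category
    'lost' selects parent-level HOG ids instead."""
    from .hog_levels import EVENTS, classify_events

    bad = set(categories) - set(EVENTS)
    if bad:
        raise ValidationError(f"unknown event categories: {sorted(bad)}")
    events, lost = classify_events(forest, tree, level, parent_level)
    out = {h for h, e in events.items() if e in categories}
    if "lost" in categories:
        out |= set(lost)
    return out
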