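# Methods

## Ancestral genomes from hierarchical orthologous groups

The unit of reconstruction is the gene family tree implicit in nested
ortholog/paralog groups: ortholog-group nodes carry a taxonomic level (an
internal node of the species tree), paralog-group nodes mark duplications,
leaves are extant genes. The ancestral genome at level `L` is the set of
*deepest* group nodes whose level is an ancestor of (or equal to) `L` and
whose members intersect the clade of `L`, with membership restricted to the
clade. Descending through a duplication that predates `L` yields one
ancestral gene per surviving copy; a duplication inside the clade leaves the
family as a single ancestral gene at `L`. Levels come from an explicit
`TaxRange` property when the OrthoXML provides one, otherwise from the LCA
of the member species.

**Completeness score.** `C = s/S`, species present in the HOG over species
of the clade, computed as an exact rational. `S` counts species present in
the input genome set under the level node, not all described species. The
default reporting filter is `C ≥ 0.3`; low-completeness HOGs imply many
independent losses and are more likely inference artifacts.

**Branch events.** For a level `L` and its most recent ancestral level `P`:
a level gene whose chain of group ancestors reaches a `P`-level gene is
*retained* if it is that gene's only level descendant and *duplicated* if at
least two level genes descend from the same `P` gene (all siblings are
labeled). A family whose topmost level lies on the branch (inclusive of `L`)
is *gained*. A `P` gene with no level descendant and no extant member inside
the clade of `L` is *lost*. A duplication of which only one copy survives at
`L` is deliberately labeled retained — the surviving lineage is in single
copy on the displayed branch; the alternative convention (label it
duplicated) is not used. These definitions make the accounting exact: every
parent gene is hit by retained/duplicated descendants or is lost, and every
level gene gets exactly one label.

**Singletons.** A family witnessed by a single extant gene cannot witness
any ancestor; such genes never appear in internal ancestral genomes.

## Ancestral gene order

Extant gene orders are projected onto the level HOGs: each gene is replaced
by its level HOG id and unmapped genes are removed *closing the gap*, so
lineage-specific insertions do not break ancestral adjacencies. Every
consecutive pair in a projected contig contributes one supporting context to
the unordered edge between two HOGs — counted per occurrence, not per
genome, so a pair present on two contigs of one genome counts twice. Tandem
repetitions of the same HOG are skipped (no self edges). Strand is recorded
on input but ignored: adjacencies are unordered neighborhood relations.

**Linearization.** Ancestral contigs are the paths of a maximum-weight
linear subgraph (every node of degree ≤ 2, no cycles) of the adjacency
graph, after dropping edges below `min_weight` (default 1 — every supporting
context is evidence). Connected components of up to 9 nodes are solved
exactly by dynamic programming over vertex subsets (enumerating the simple
path containing the lowest-indexed vertex and recursing on the rest); among
equal-weight optima the lexicographically smallest sorted edge list is
chosen, which fixes deterministically, e.g., which edge of an all-tied cycle
is dropped. Larger components use a greedy rule — accept edges by descending
weight (ties: lexicographically smaller node pair) while both endpoints keep
degree < 2 and no cycle forms — which is exact on the near-path components
that real adjacency evidence produces and near-optimal otherwise. Pure-cycle
components (plasmid-like) are linearized by dropping their lightest
adjacency and flagged circular. Contigs are reported by decreasing length,
ties by smallest HOG id, each path oriented to start at its
lexicographically smaller endpoint.

**Synteny windows.** The viewer shows the focal ancestral gene with up to
`window` (default 5) inferred flanking HOGs in both directions, then one row
per extant genome of the clade (the neighborhoods of the focal HOG's member
genes) or, for collapsed internal nodes, the neighborhood of the
corresponding ancestral gene in that node's own reconstruction. Entries are
colored by the reference-level HOG their family maps to; entries with no
homology at the reference level are grey. Genomes lacking a member of the
focal family contribute no row.

## GO propagation and term statistics

A leaf gene's profile is the upward closure of its annotations under
is_a/part_of (the true-path rule). Bottom-up, a node's support for term `t`
is the fraction of its children that carry `t`, where a child carries `t`
iff it is itself annotated with `t` (leaf: closure membership; internal:
its own support reached τ). The node is annotated when support ≥ τ
(default 0.5). This recursive-threshold reading was chosen over "any leaf of
the subtree contains `t`" because the latter lets a term fail at a node yet
reappear at its parent. Children are weighted equally regardless of subtree
size so large clades cannot dominate (`weight_by_size` switches to
member-count weights). The rule is a deliberately parameter-light,
parsimony-flavored simplification of weighted belief-propagation annotation
transfer; τ is exposed for study. Emitted annotations keep, per node, only
the most specific terms: an ancestor term is reported only when its support
strictly exceeds that of every annotated descendant term.

Term statistics over a corpus: `count(t)` = subjects whose closure contains
`t`; `p(t) = count(t)/count(root of t's namespace)`; information content
`IC(t) = −ln p(t)` (natural log, as in the simRel literature). By closure,
`p` is monotone non-decreasing toward the root, the root has `p = 1`,
`IC = 0`.

## Enrichment

One-sided over-representation only: `p = P[X ≥ n_study]` with
`X ~ Hypergeom(N_pop, n_pop, N_study)` (scipy's hypergeometric survival
function; an exhaustive rational-arithmetic sweep over all tables with
`N_pop ≤ 60` bounds the error at ~4e-16). The population is *all* subjects
of the background — all genes of the genome, or all HOGs defined at the
level — annotated or not. The test universe is the set of terms carried by
at least one study subject after closure (`m` = its size); terms absent from
the study cannot be one-sidedly over-represented, but `--test-universe
population` switches to all population terms. Bonferroni is `min(1, p·m)`;
Benjamini–Hochberg is the step-up adjustment reported in input order. The
default report filter is BH ≤ 0.05. Ancestral mode requires all study HOG
ids to exist at one stated level; extant mode reports the taxonomic level
implied by the study species (their LCA).

## Semantic maps

For each namespace with at least one significant term, pairwise simRel is
computed with `p` taken from the enrichment population corpus (the analysis
is self-contained; no global annotation database is assumed). Self-similarity
`1 − p(t)` is normalized to 1 (cosine-style, so duplicated terms coincide),
distances `d = 1 − sim` are embedded by classical (Torgerson) MDS — double
centering, symmetric eigendecomposition, top two axes scaled by the square
root of their (non-negative-clipped) eigenvalues. The embedding is
deterministic bit-for-bit: `numpy.linalg.eigh` plus a sign convention making
the largest-magnitude entry of each axis positive. Classical MDS was chosen
over iterative stress majorization precisely for this reproducibility; for
three points with Euclidean-consistent distances it is exact.

## The simulator

The generator emulates gene-content and gene-order evolution of a clade:
one ordered root chromosome of `n_ancestral_genes` (default 100) evolves
down a balanced/caterpillar/random tree of `n_species` (default 8); per
branch, in order: duplications (Poisson, mean 1.0; copy inserted adjacent to
its template so zero-inversion simulations stay collinear), gains (Poisson,
mean 2.0; uniform position), losses (Poisson, mean 2.0; uniform deletion)
and a fixed number of inversions (default 1; uniform interval reversed).
The ontology is a layered random DAG under the three GO namespace roots
(default 60 terms; leaf terms get an is_a parent and occasionally a part_of
second parent); each family carries `terms_per_gene` (default 2) leaf terms
inherited by all descendants, plus spurious leaf annotations at rate
`annotation_noise` (default 0.05). One integer seed fixes every draw;
identical configs are byte-identical.

Emitted OrthoXML carries the *true* group structure: an ortholog group with
its true `TaxRange` at every internal node where the lineage existed,
duplications as paralog groups. The ground truth (per-ancestor content,
order, per-branch events, term sets) is pruned to lineages with at least one
extant descendant, so it is exactly what an ideal observer of the emitted
files could know; terminal-branch gains are emitted as singleton genes
outside any group. What the simulator does **not** model: sequences,
unequal rates across branches or families, multi-chromosome karyotype
evolution, horizontal transfer, translocations between contigs, or
annotation incompleteness structured by evidence code. Passing
planted-recovery tests therefore shows the algorithms are correct under
their own assumptions, not that real HOG inference is error-free —
completeness filtering exists precisely because real input groups are noisy.

## Problem sizes and numerical choices

Default analysis sizes (8 species, ~100 families, ~60 terms) keep every
planted-recovery run in seconds while exercising all code paths; the
statistical checks use exhaustive sweeps (all Fisher tables to `N_pop ≤ 60`)
or 100–1000 seeded replicates, sizes chosen so each oracle comparison is
exact rather than sampled where exactness is feasible. Exact rational
arithmetic (`fractions.Fraction`) is used for completeness scores,
propagation supports and test oracles; floats only where scipy/numpy
operate. Degenerate inputs are defined, not special-cased: empty
projections contribute nothing, a focal HOG on no contig yields a
single-column view with a warning flag, fewer than two terms embed at the
origin with a degeneracy flag, and an empty annotation corpus is an error.

## Known limitations

- Gene order is reconstructed without orientation and without rearrangement
  scenarios (no DCJ/inversion histories).
- The greedy linearization fallback for components larger than 9 nodes can
  be suboptimal on dense tangles of conflicting adjacencies.
- Propagation is upward only; genes are never annotated from ancestors.
- The hierarchical id grammar (`HOG:<root>.<k><letter>` per duplication) is
  a compatible reading of the common convention; other producers may suffix
  differently, in which case ids are preserved only at family roots.
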