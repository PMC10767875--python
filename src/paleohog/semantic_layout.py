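"""Semantic maps of enriched GO terms: simRel similarity, classical MDS, bubbles.

simRel between two terms combines Lin-style normalization with the relevance
(1 - p) of their most informative common ancestor:

    simRel(t1, t2) = max over common ancestors a of
                     [ 2 ln p(a) / (ln p(t1) + ln p(t2)) ] * (1 - p(a))

Terms count as their own ancestors, so simRel(t, t) = 1 - p(t); a pair whose
only shared ancestor is the namespace root (p = 1) scores 0.  Significant
terms of each namespace are embedded in 2-D with classical (Torgerson) metric
MDS on d = 1 - normalized similarity; the embedding is deterministic up to
the fixed sign convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .enrichment import EnrichmentResult, EnrichmentRow
from .go_propagation import TermStats
from .model import GeneOntology, ValidationError


def simrel(t1: str, t2: str, stats: TermStats, ontology: GeneOntology) -> float:
    """simRel semantic similarity in [0, 1] between two same-namespace terms."""
    t1, t2 = ontology.resolve(t1), ontology.resolve(t2)
    if ontology.namespace(t1) != ontology.namespace(t2):
        raise ValidationError(
            f"simRel across namespaces: {t1} ({ontology.namespace(t1)}) vs "
            f"{t2} ({ontology.namespace(t2)})"
        )
    common = (ontology.ancestors(t1) | {t1}) & (ontology.ancestors(t2) | {t2})
    ln1 = math.log(stats.probability(t1))
    ln2 = math.log(stats.probability(t2))
    denom = ln1 + ln2
    best = 0.0
    for a in common:
        if a not in stats:
            continue
        pa = stats.probability(a)
        if pa >= 1 or denom == 0:
            continue  # the namespace root (or two root terms) contributes 0
        score = (2 * math.log(pa) / denom) * (1 - pa)
        best = max(best, score)
    return min(1.0, best)


def simrel_matrix(terms: list[str], stats: TermStats, ontology: GeneOntology) -> np.ndarray:
    n = len(terms)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            sim[i, j] = sim[j, i] = simrel(terms[i], terms[j], stats, ontology)
    return sim


def normalize_self_similarity(sim: np.ndarray) -> np.ndarray:
    """Scale so every self-similarity is 1 (identical terms then coincide
    at distance 0); terms with zero self-similarity stay dissimilar to all."""
    diag = np.diag(sim).copy()
    n = sim.shape[0]
    out = np.zeros_like(sim)
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
            elif diag[i] > 0 and diag[j] > 0:
                out[i, j] = min(1.0, sim[i, j] / math.sqrt(diag[i] * diag[j]))
    return out


def mds_embed(similarities: np.ndarray) -> tuple[np.ndarray, bool]:
    """Classical (Torgerson) metric MDS of d = 1 - similarity into 2-D.

    Returns (coordinates, degenerate).  Deterministic: eigendecomposition via
    numpy.linalg.eigh plus a sign convention forcing the entry of largest
    magnitude on each axis positive.  Fewer than two points embed at the
    origin with the degenerate flag set.
    """
    sim = np.asarray(similarities, dtype=float)
    n = sim.shape[0]
    if sim.shape != (n, n) or not np.allclose(sim, sim.T, atol=1e-12):
        raise ValidationError("similarity matrix must be square and symmetric")
    if n and np.abs(np.diag(sim) - 1).max() > 1e-9:
        raise ValidationError("similarity matrix must have unit diagonal")
    if n < 2:
        return np.zeros((n, 2)), True
    d = 1.0 - sim
    d2 = d * d
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:2]
    coords = np.zeros((n, 2))
    for axis, k in enumerate(order):
        lam = max(eigval[k], 0.0)
        coords[:, axis] = eigvec[:, k] * math.sqrt(lam)
    for axis in range(2):
        col = coords[:, axis]
        if col.any():
            pivot = int(np.argmax(np.abs(col)))
            if col[pivot] < 0:
                coords[:, axis] = -col
    return coords, False


@dataclass
class SemanticPoint:
    term_id: str
    name: str
    x: float
    y: float
    corrected_p: float
    information_content: float


@dataclass
class SemanticMap:
    namespace: str
    points: list[SemanticPoint]
    degenerate: bool = False

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "term": p.term_id,
                    "name": p.name,
                    "x": p.x,
                    "y": p.y,
                    "p_corrected": p.corrected_p,
                    "ic": p.information_content,
                }
                for p in self.points
            ],
            indent=2,
        )


def export_map(
    result: EnrichmentResult, stats: TermStats, ontology: GeneOntology
) -> dict[str, SemanticMap]:
    """Build up to three semantic maps (one per namespace with >=1 significant
    term) from an enrichment result.  Bubble payloads carry the term name,
    id, corrected p-value and information content."""
    by_ns: dict[str, list[EnrichmentRow]] = {}
    for row in result.rows:
        by_ns.setdefault(row.namespace, []).append(row)
    corrected = (
        (lambda r: r.p_bh) if result.method == "bh" else (lambda r: r.p_bonferroni)
    )
    maps: dict[str, SemanticMap] = {}
    for ns in sorted(by_ns):
        rows = sorted(by_ns[ns], key=lambda r: r.term_id)
        terms = [r.term_id for r in rows]
        usable = [t for t in terms if t in stats]
        rows = [r for r in rows if r.term_id in stats]
        sim = simrel_matrix(usable, stats, ontology)
        coords, degenerate = mds_embed(normalize_self_similarity(sim))
        points = [
            SemanticPoint(
                term_id=r.term_id,
                name=r.name,
                x=float(coords[i, 0]),
                y=float(coords[i, 1]),
                corrected_p=corrected(r),
                information_content=stats.information_content(r.term_id),
            )
            for i, r in enumerate(rows)
        ]
        maps[ns] = SemanticMap(namespace=ns, points=points, degenerate=degenerate)
    return maps


def plot_map(semantic_map: SemanticMap, path: str) -> None:
    """Static bubble plot: position = semantic space, size = information
    content, color = corrected p-value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p.x for p in semantic_map.points]
    ys = [p.y for p in semantic_map.points]
    ics = [p.information_content for p in semantic_map.points]
    ps = [p.corrected_p for p in semantic_map.points]
    fig, ax = plt.subplots(figsize=(6, 5))
    sizes = [60 + 60 * ic for ic in ics]
    sc = ax.scatter(xs, ys, s=sizes, c=ps, cmap="viridis_r", alpha=0.8,
                    edgecolors="black", linewidths=0.5)
    for p in semantic_map.points:
        ax.annotate(p.term_id, (p.x, p.y), fontsize=6, ha="center", va="bottom")
    fig.colorbar(sc, ax=ax, label="corrected p-value")
    ax.set_xlabel("semantic dimension 1")
    ax.set_ylabel("semantic dimension 2")
    ax.set_title(f"{semantic_map.namespace} enriched terms")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
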