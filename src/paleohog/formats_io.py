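"""Readers and writers for the four standard inputs and all result tables.

Formats: Newick (species tree), OrthoXML 0.3/0.4 (hierarchical orthologous
groups), GFF3 or a simple TSV dialect (extant gene orders), OBO 1.2/1.4 and
GAF 2.x (Gene Ontology and gene annotations).  All result writers emit TSV
with a commented header line naming the tool version.
"""

from __future__ import annotations

import io
import re
import string
from dataclasses import dataclass, field

import dendropy
import networkx as nx
import obonet
from lxml import etree

from . import __version__
from .model import (
    LEAF_GENE,
    ORTHOLOG,
    PARALOG,
    AnnotationRow,
    AnnotationTable,
    ExtantGenome,
    GeneOntology,
    GeneRecord,
    HOGForest,
    HOGNode,
    NewickParseError,
    SpeciesTree,
    TaxonNode,
    TermRecord,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Newick species tree


def parse_species_tree(newick_text: str) -> SpeciesTree:
    """Parse a rooted Newick tree into a SpeciesTree.

    Unlabeled internal nodes are auto-named N1, N2, ... in preorder; unary
    chains are collapsed (keeping the label closest to the root).  A tree
    whose root would end up with fewer than two children is rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate labels in Newick: {exc}") from None
        raise NewickParseError(f"malformed Newick: {exc}") from None

    def label_of(dnode) -> str | None:
        if dnode.taxon is not None and dnode.taxon.label:
            return dnode.taxon.label
        return dnode.label or None

    def convert(dnode, parent: TaxonNode | None) -> TaxonNode:
        children = dnode.child_nodes()
        if len(children) == 1:
            # collapse unary chain; an upper label survives onto an unlabeled child
            child = convert(children[0], parent)
            if label_of(dnode) and child.children and label_of(children[0]) is None:
                child.name = label_of(dnode)
            return child
        node = TaxonNode(label_of(dnode) or "", parent)
        for c in children:
            node.children.append(convert(c, node))
        return node

    root = convert(dtree.seed_node, None)
    if root.is_leaf or len(root.children) < 2:
        raise ValidationError("species tree must have an internal root with >=2 children")

    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.is_leaf and not node.name:
            counter += 1
            node.name = f"N{counter}"
        stack.extend(reversed(node.children))
    return SpeciesTree(root)


def serialize_species_tree(tree: SpeciesTree) -> str:
    def render(node: TaxonNode) -> str:
        if node.is_leaf:
            return node.name
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){node.name}"

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# OrthoXML HOGs

_DUP_SUFFIX_LETTERS = string.ascii_lowercase


def _dup_letter(i: int) -> str:
    if i < 26:
        return _DUP_SUFFIX_LETTERS[i]
    return _DUP_SUFFIX_LETTERS[i // 26 - 1] + _DUP_SUFFIX_LETTERS[i % 26]


def assign_hog_ids(root: HOGNode, root_id: str) -> None:
    """Assign hierarchical HOG identifiers under one family root.

    The root id is propagated through speciation nodes unchanged; the children
    of the k-th duplication under a given id receive suffixes .<k>a, .<k>b, ...
    in document order (e.g. HOG:D0639603.1b is the second copy of the first
    duplication of HOG:D0639603).
    """
    dup_counter: dict[str, int] = {}

    def walk(node: HOGNode, current_id: str) -> None:
        node.hog_id = current_id
        for child in node.children:
            if child.kind == PARALOG:
                k = dup_counter.get(current_id, 0) + 1
                dup_counter[current_id] = k
                child.hog_id = current_id
                for i, copy in enumerate(child.children):
                    walk(copy, f"{current_id}.{k}{_dup_letter(i)}")
            else:
                walk(child, current_id)

    walk(root, root_id)


def _local_name(elem) -> str:
    return etree.QName(elem).localname


def parse_hogs(orthoxml_text: str, tree: SpeciesTree) -> HOGForest:
    """Parse nested orthologGroup/paralogGroup elements into a HOGForest.

    Levels come from an explicit ``TaxRange`` property when present, otherwise
    from the LCA of the member species in the species tree.  HOG ids preserve
    the root group's ``id`` attribute when present, else HOG:R<k>.
    """
    try:
        doc = etree.fromstring(orthoxml_text.encode())
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"malformed OrthoXML: {exc}") from None

    # map internal geneRef ids -> (gene_id, species)
    gene_map: dict[str, tuple[str, str]] = {}
    for species_el in doc.iter():
        if _local_name(species_el) != "species":
            continue
        sp_name = species_el.get("name")
        for gene_el in species_el.iter():
            if _local_name(gene_el) == "gene":
                gid = gene_el.get("protId") or gene_el.get("geneId") or gene_el.get("id")
                gene_map[gene_el.get("id")] = (gid, sp_name)

    unknown_species = sorted(
        {sp for _, sp in gene_map.values() if sp not in tree}
    )
    if unknown_species:
        raise ValidationError(
            f"species in OrthoXML absent from species tree: {unknown_species}"
        )

    def build(elem) -> HOGNode:
        name = _local_name(elem)
        if name == "geneRef":
            ref = elem.get("id")
            if ref not in gene_map:
                raise ValidationError(f"geneRef {ref!r} resolves to no genome gene")
            gid, sp = gene_map[ref]
            return HOGNode(LEAF_GENE, gene_id=gid, species=sp)
        if name == "orthologGroup":
            node = HOGNode(ORTHOLOG)
            tax_range = None
            for child in elem:
                cname = _local_name(child)
                if cname == "property":
                    if child.get("name") in ("TaxRange", "TaxId", "taxon"):
                        tax_range = child.get("value")
                elif cname in ("orthologGroup", "paralogGroup", "geneRef"):
                    node.add_child(build(child))
            if not node.children:
                raise ValidationError("empty orthologGroup")
            if tax_range is not None:
                if tax_range not in tree:
                    raise ValidationError(f"TaxRange {tax_range!r} not in species tree")
                node.level = tax_range
            else:
                node.level = tree.lca(node.member_species())
            for _, sp in node.members():
                if not tree.is_ancestor_or_equal(node.level, sp):
                    raise ValidationError(
                        f"member species {sp!r} outside clade of level {node.level!r}"
                    )
            return node
        if name == "paralogGroup":
            node = HOGNode(PARALOG)
            for child in elem:
                cname = _local_name(child)
                if cname in ("orthologGroup", "paralogGroup", "geneRef"):
                    node.add_child(build(child))
            if len(node.children) < 2:
                raise ValidationError("paralogGroup needs >=2 children")
            return node
        raise ValidationError(f"unexpected element {name!r} inside groups")

    groups_el = None
    for el in doc.iter():
        if _local_name(el) == "groups":
            groups_el = el
            break
    if groups_el is None:
        raise ValidationError("OrthoXML has no <groups> section")

    roots: list[HOGNode] = []
    for k, top in enumerate(
        el for el in groups_el if _local_name(el) == "orthologGroup"
    ):
        node = build(top)
        root_id = top.get("id") or f"HOG:R{k + 1}"
        assign_hog_ids(node, root_id)
        # paralog levels: inherit the enclosing ortholog level
        for n in node.iter_nodes():
            if n.kind == PARALOG and n.parent is not None:
                n.level = n.parent.level
        roots.append(node)
    return HOGForest(roots)


def serialize_hogs(forest: HOGForest, tree: SpeciesTree) -> str:
    """Write a HOGForest as OrthoXML 0.4 (genes grouped per species)."""
    NS = "http://orthoXML.org/2011/"
    root = etree.Element(f"{{{NS}}}orthoXML", version="0.4", origin="paleohog",
                         originVersion=__version__)
    by_species: dict[str, list[str]] = {}
    for gid, node in sorted(forest.gene_index.items()):
        by_species.setdefault(node.species, []).append(gid)
    ref_ids: dict[str, str] = {}
    next_ref = 1
    for sp in sorted(by_species):
        sp_el = etree.SubElement(root, f"{{{NS}}}species", name=sp, NCBITaxId="0")
        db_el = etree.SubElement(sp_el, f"{{{NS}}}database", name="paleohog", version="1")
        genes_el = etree.SubElement(db_el, f"{{{NS}}}genes")
        for gid in by_species[sp]:
            ref_ids[gid] = str(next_ref)
            etree.SubElement(genes_el, f"{{{NS}}}gene", id=str(next_ref), protId=gid)
            next_ref += 1
    groups_el = etree.SubElement(root, f"{{{NS}}}groups")

    def emit(node: HOGNode, parent_el, is_root: bool = False) -> None:
        if node.kind == LEAF_GENE:
            etree.SubElement(parent_el, f"{{{NS}}}geneRef", id=ref_ids[node.gene_id])
            return
        tag = "orthologGroup" if node.kind == ORTHOLOG else "paralogGroup"
        el = etree.SubElement(parent_el, f"{{{NS}}}{tag}")
        if is_root and node.hog_id:
            el.set("id", node.hog_id)
        if node.kind == ORTHOLOG and node.level:
            etree.SubElement(el, f"{{{NS}}}property", name="TaxRange", value=node.level)
        for child in node.children:
            emit(child, el)

    for r in forest.roots:
        emit(r, groups_el, is_root=True)
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


# ---------------------------------------------------------------------------
# Gene orders


def parse_gene_orders(
    text: str, format: str = "tsv", species: str | None = None
) -> list[ExtantGenome]:
    """Parse extant gene orders from GFF3 or the TSV dialect.

    TSV columns: species, contig, start, gene_id[, strand]; lines starting
    with '#' are comments.  GFF3 rows of type ``gene`` are used; coordinates
    are converted from 1-based inclusive to 0-based half-open; a GFF3 file
    describes a single genome whose species must be given.
    """
    records: dict[str, dict[str, list[GeneRecord]]] = {}

    def add(sp: str, contig: str, start: int, gid: str, strand: str) -> None:
        records.setdefault(sp, {}).setdefault(contig, []).append(
            GeneRecord(gid, sp, contig, start, strand=strand)
        )

    if format == "tsv":
        for line in text.splitlines():
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"gene-order TSV row has <4 columns: {line!r}")
            sp, contig, start, gid = parts[:4]
            strand = parts[4] if len(parts) > 4 else "."
            add(sp, contig, int(start), gid, strand)
    elif format == "gff3":
        if species is None:
            raise ValidationError("GFF3 input requires an explicit species name")
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name")
            if gid is None:
                raise ValidationError(f"GFF3 gene row without ID attribute: {line!r}")
            add(species, parts[0], int(parts[3]) - 1, gid, parts[6])
    else:
        raise ValidationError(f"unknown gene-order format: {format!r}")

    return [ExtantGenome(sp, contigs) for sp, contigs in sorted(records.items())]


def serialize_gene_orders(genomes: list[ExtantGenome]) -> str:
    lines = [f"# paleohog {__version__}", "# species\tcontig\tstart\tgene_id\tstrand"]
    for genome in genomes:
        for contig in sorted(genome.contigs):
            for g in genome.contigs[contig]:
                lines.append(f"{g.species}\t{g.contig}\t{g.start}\t{g.gene_id}\t{g.strand}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Ontology (OBO) and annotations (GAF)


def parse_ontology(obo_text: str) -> GeneOntology:
    """Parse an OBO 1.2/1.4 ontology; is_a and part_of become parent edges."""
    graph = obonet.read_obo(io.StringIO(obo_text), ignore_obsolete=False)
    terms: dict[str, TermRecord] = {}
    alt_ids: dict[str, str] = {}
    for term_id, data in graph.nodes(data=True):
        parents: set[str] = set()
        for _, parent, rel in graph.out_edges(term_id, keys=True):
            if rel in ("is_a", "part_of"):
                parents.add(parent)
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms[term_id] = TermRecord(
            term_id=term_id,
            name=data.get("name", term_id),
            namespace=data.get("namespace", ""),
            parents=frozenset(parents if not obsolete else ()),
            obsolete=obsolete,
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term_id
    simple = nx.DiGraph(
        (t, p) for t, rec in terms.items() for p in rec.parents
    )
    if not nx.is_directed_acyclic_graph(simple):
        raise ValidationError("ontology contains a cycle")
    return GeneOntology(terms, alt_ids)


@dataclass
class GafResult:
    table: AnnotationTable
    n_skipped_unknown: int = 0
    n_dropped_not: int = 0
    n_dropped_nd: int = 0


def parse_gaf(gaf_text: str, ontology: GeneOntology) -> GafResult:
    """Parse GAF 2.x rows into a non-redundant AnnotationTable.

    Rows with a NOT qualifier or ND evidence are dropped; rows whose GO id is
    unknown (after alt_id resolution) or obsolete are skipped with a count.
    """
    rows: list[AnnotationRow] = []
    n_unknown = n_not = n_nd = 0
    for line in gaf_text.splitlines():
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            continue
        subject, qualifier, go_id, evidence = cols[1], cols[3], cols[4], cols[6]
        if "NOT" in qualifier.split("|"):
            n_not += 1
            continue
        if evidence == "ND":
            n_nd += 1
            continue
        if go_id not in ontology:
            n_unknown += 1
            continue
        if ontology.term(go_id).obsolete:
            n_unknown += 1
            continue
        rows.append(AnnotationRow(subject, ontology.resolve(go_id), evidence))
    return GafResult(AnnotationTable(rows, ontology), n_unknown, n_not, n_nd)


# ---------------------------------------------------------------------------
# Result tables


def write_tsv(path, header: list[str], rows: list[tuple]) -> None:
    """Write a result TSV with a version comment line."""
    with open(path, "w") as fh:
        fh.write(f"# paleohog {__version__}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def format_tsv(header: list[str], rows: list[tuple]) -> str:
    out = [f"# paleohog {__version__}", "\t".join(header)]
    out.extend("\t".join(str(v) for v in row) for row in rows)
    return "\n".join(out) + "\n"
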