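"""Shared fixtures: a tiny hand-built clade and ontology, plus simulations."""

from __future__ import annotations

import pytest

from paleohog.formats_io import parse_gaf, parse_hogs, parse_ontology, parse_species_tree


def make_orthoxml(genes: list[tuple[str, str]], groups_body: str) -> str:
    """Build a minimal OrthoXML document.

    ``genes`` lists (species, gene_id) pairs; the geneRef id of the i-th pair
    is i+1.  ``groups_body`` is the literal XML inside <groups>.
    """
    by_species: dict[str, list[tuple[int, str]]] = {}
    for i, (sp, gid) in enumerate(genes):
        by_species.setdefault(sp, []).append((i + 1, gid))
    species_blocks = []
    for sp in by_species:
        rows = "".join(
            f'<gene id="{ref}" protId="{gid}"/>' for ref, gid in by_species[sp]
        )
        species_blocks.append(
            f'<species name="{sp}" NCBITaxId="0"><database name="t" version="1">'
            f"<genes>{rows}</genes></database></species>"
        )
    return (
        '<?xml version="1.0"?>\n'
        '<orthoXML xmlns="http://orthoXML.org/2011/" version="0.4" origin="test" originVersion="1">'
        + "".join(species_blocks)
        + f"<groups>{groups_body}</groups></orthoXML>"
    )


TINY_NEWICK = "((A,B)AB,C)ROOT;"

# six-term BP DAG (diamond through A/B plus a chain), one MF root, one
# obsolete term, one alt_id — enough to exercise closure, simRel and aliasing
TINY_OBO = """format-version: 1.2
ontology: tiny

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0000002
name: branch A
namespace: biological_process
is_a: GO:0008150 ! root

[Term]
id: GO:0000003
name: branch B
namespace: biological_process
alt_id: GO:0000001
is_a: GO:0008150 ! root

[Term]
id: GO:0000004
name: node C
namespace: biological_process
is_a: GO:0000002 ! branch A
relationship: part_of GO:0000003 ! branch B

[Term]
id: GO:0000005
name: leaf D
namespace: biological_process
is_a: GO:0000004 ! node C

[Term]
id: GO:0000006
name: leaf E
namespace: biological_process
is_a: GO:0000003 ! branch B

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0000007
name: mf leaf
namespace: molecular_function
is_a: GO:0003674 ! mf root

[Term]
id: GO:0000099
name: gone
namespace: biological_process
is_obsolete: true

[Typedef]
id: part_of
name: part of
"""


@pytest.fixture(scope="session")
def tiny_tree():
    return parse_species_tree(TINY_NEWICK)


@pytest.fixture(scope="session")
def tiny_ontology():
    return parse_ontology(TINY_OBO)


@pytest.fixture(scope="session")
def tiny_forest(tiny_tree):
    """One family over all three species with a duplication below AB, plus a
    C-only family; levels left to LCA inference except the explicit root."""
    xml = make_orthoxml(
        [("A", "a1"), ("B", "b1"), ("A", "a2"), ("B", "b2"), ("C", "c1"),
         ("C", "c2"), ("A", "a3")],
        """
        <orthologGroup id="HOG:T001">
          <property name="TaxRange" value="ROOT"/>
          <geneRef id="5"/>
          <paralogGroup>
            <orthologGroup><geneRef id="1"/><geneRef id="2"/></orthologGroup>
            <orthologGroup><geneRef id="3"/><geneRef id="4"/></orthologGroup>
          </paralogGroup>
        </orthologGroup>
        <orthologGroup id="HOG:T002">
          <property name="TaxRange" value="ROOT"/>
          <geneRef id="6"/>
          <orthologGroup><geneRef id="7"/></orthologGroup>
        </orthologGroup>
        """,
    )
    # second family is a ROOT-level group surviving in C and A only
    return parse_hogs(xml, tiny_tree)


def simulate_parsed(**overrides):
    """Run the simulator and parse everything back through formats_io."""
    from paleohog.simulate import SimulationConfig, simulate
    from paleohog.formats_io import parse_gene_orders

    out = simulate(SimulationConfig(**overrides))
    tree = parse_species_tree(out.newick)
    forest = parse_hogs(out.orthoxml, tree)
    genomes = parse_gene_orders(out.gene_orders_tsv)
    ontology = parse_ontology(out.obo)
    gaf = parse_gaf(out.gaf, ontology)
    return out, tree, forest, genomes, ontology, gaf


@pytest.fixture(scope="session")
def null_sim():
    """No events at all: every extant genome equals the root genome."""
    return simulate_parsed(
        n_species=4,
        n_ancestral_genes=12,
        gain_rate=0,
        loss_rate=0,
        duplication_rate=0,
        n_inversions=0,
        annotation_noise=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def mixed_sim():
    """All event types active; used for invariant checks."""
    return simulate_parsed(
        n_species=8,
        n_ancestral_genes=40,
        gain_rate=1.5,
        loss_rate=1.5,
        duplication_rate=1.0,
        n_inversions=1,
        seed=7,
    )
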