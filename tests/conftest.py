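import numpy as np
import pytest

from semprop.fixtures import (
    make_linear_chain,
    make_phospho_pair,
    make_random_model,
    make_reaction_pair,
    rename_model,
)

#: minimal hand-written SBML Level 2 file: one reaction A -> B, species A
#: annotated in both MIRIAM URI dialects with two resources for one sugar.
TOY_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="toy">
    <listOfCompartments>
      <compartment id="cell" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" metaid="meta_A">
        <annotation>
          <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                   xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">
            <rdf:Description rdf:about="#meta_A">
              <bqbiol:is>
                <rdf:Bag>
                  <rdf:li rdf:resource="urn:miriam:chebi:CHEBI%3A17925"/>
                  <rdf:li rdf:resource="http://identifiers.org/kegg.compound/C00267"/>
                </rdf:Bag>
              </bqbiol:is>
            </rdf:Description>
          </rdf:RDF>
        </annotation>
      </species>
      <species id="B" compartment="cell"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="r1" reversible="false">
        <listOfReactants><speciesReference species="A"/></listOfReactants>
        <listOfProducts><speciesReference species="B"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


@pytest.fixture
def toy_sbml_path(tmp_path):
    path = tmp_path / "toy.xml"
    path.write_text(TOY_SBML)
    return path


@pytest.fixture
def chain_pair():
    """Two copies of the endpoint-annotated linear chain (distinct model ids)."""
    a = make_linear_chain(5, model_id="chainA")
    return a, rename_model(a, "chainB")


@pytest.fixture
def reaction_pair():
    return make_reaction_pair()


@pytest.fixture
def phospho_pair():
    return make_phospho_pair()


@pytest.fixture
def random_model_pair():
    a = make_random_model(10, 7, 1.0, concept_pool_size=40, seed=7, model_id="benchA")
    return a, rename_model(a, "benchB")


def neumann_series(A, rhs, lam, steps):
    """Independent dense truncated-series oracle: sum_{k=0..K} (lam A)^k rhs."""
    A = np.asarray(A if not hasattr(A, "toarray") else A.toarray(), dtype=float)
    term = np.asarray(rhs, dtype=float).copy()
    acc = term.copy()
    for _ in range(steps):
        term = lam * (A @ term)
        acc = acc + term
    return acc
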