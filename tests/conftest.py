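import numpy as np
import pytest

from comatch.config import MatcherConfig
from comatch.ontology_io import Concept, Ontology
from comatch.similarity import SimilarityParams, SynonymProvider


RDFXML_3CLASS = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
         xmlns:owl="http://www.w3.org/2002/07/owl#">
  <owl:Class rdf:about="http://example.org/onto#A">
    <rdfs:label>Heart</rdfs:label>
    <rdfs:comment>A muscular organ</rdfs:comment>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/onto#B">
    <rdfs:label>Myocardium</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/onto#A"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/onto#C">
    <rdfs:label>Pericardium</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/onto#A"/>
  </owl:Class>
  <owl:ObjectProperty rdf:about="http://example.org/onto#hasWall">
    <rdfs:label>has wall</rdfs:label>
    <rdfs:domain rdf:resource="http://example.org/onto#B"/>
    <rdfs:range rdf:resource="http://example.org/onto#C"/>
  </owl:ObjectProperty>
</rdf:RDF>
"""

TURTLE_3CLASS = """@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix ex: <http://example.org/onto#> .

ex:A a owl:Class ;
    rdfs:label "Heart" ;
    rdfs:comment "A muscular organ" .

ex:B a owl:Class ;
    rdfs:label "Myocardium" ;
    rdfs:subClassOf ex:A .

ex:C a owl:Class ;
    rdfs:label "Pericardium" ;
    rdfs:subClassOf ex:A .

ex:hasWall a owl:ObjectProperty ;
    rdfs:label "has wall" ;
    rdfs:domain ex:B ;
    rdfs:range ex:C .
"""


@pytest.fixture
def rdfxml_file(tmp_path):
    path = tmp_path / "onto.owl"
    path.write_text(RDFXML_3CLASS)
    return path


@pytest.fixture
def turtle_file(tmp_path):
    path = tmp_path / "onto.ttl"
    path.write_text(TURTLE_3CLASS)
    return path


@pytest.fixture
def sim_params():
    return SimilarityParams()


@pytest.fixture
def empty_syn():
    return SynonymProvider()


@pytest.fixture
def default_cfg():
    return MatcherConfig()


def make_ontology(spec: dict[str, dict]) -> Ontology:
    """Build an ontology from {fragment: {label?, comment?, children?}}."""
    base = "http://example.org/t#"
    ontology = Ontology(id="test")
    for fragment, info in spec.items():
        labels = info.get("labels")
        if labels is None and "label" in info:
            labels = [info["label"]]
        concept = Concept(
            iri=base + fragment,
            labels=list(labels or [fragment]),
            comments=list(info.get("comments", [])),
            property_info=list(info.get("properties", [])),
            direct_descendants=[base + c for c in info.get("children", [])],
        )
        ontology.add(concept)
    return ontology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class StubRng:
    """Deterministic random source: replays injected uniform draws and
    integer picks in order."""

    def __init__(self, draws=(), integers=()):
        self._draws = list(draws)
        self._integers = list(integers)

    def random(self, n=None):
        if n is None:
            return self._draws.pop(0)
        chunk, self._draws = self._draws[:n], self._draws[n:]
        assert len(chunk) == n, "stub exhausted"
        return np.asarray(chunk)

    def integers(self, low, high=None):
        return self._integers.pop(0)
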