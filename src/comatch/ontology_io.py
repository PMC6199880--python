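"""Ontology loading and concept-profile construction.

Ontologies are read from OWL files (RDF/XML or Turtle) into a small in-memory
model: named classes with their labels, comments, attached property
information and direct subclass children. Each concept then gets a *profile*,
the multiset of normalized word tokens harvested from the concept itself and
its direct descendants; profiles are the unit of similarity for the matcher.

The parsers cover the common serialization patterns for class hierarchies
(typed nodes / ``rdf:Description`` with ``rdf:about``, ``rdfs:label``,
``rdfs:comment``, ``rdfs:subClassOf``, property declarations with
``rdfs:domain``/``rdfs:range``). They are deliberately not full RDF parsers:
anonymous classes and constructs outside this subset are skipped.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"

RDF_TYPE = RDF_NS + "type"
RDFS_LABEL = RDFS_NS + "label"
RDFS_COMMENT = RDFS_NS + "comment"
RDFS_SUBCLASSOF = RDFS_NS + "subClassOf"
RDFS_DOMAIN = RDFS_NS + "domain"
RDFS_RANGE = RDFS_NS + "range"
OWL_CLASS = OWL_NS + "Class"
OWL_THING = OWL_NS + "Thing"
_PROPERTY_TYPES = frozenset(
    {
        OWL_NS + "ObjectProperty",
        OWL_NS + "DatatypeProperty",
        OWL_NS + "AnnotationProperty",
        RDF_NS + "Property",
    }
)


class OntologyError(ValueError):
    """Raised for unusable ontology input (e.g. no named classes)."""


@dataclass
class Concept:
    """A named class with the textual information the matcher consumes."""

    iri: str
    labels: list[str] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)
    #: (property label, domain label, range label) triples for properties
    #: whose domain is this class.
    property_info: list[tuple[str, str, str]] = field(default_factory=list)
    #: IRIs of classes asserting this concept as a direct superclass.
    direct_descendants: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.iri:
            raise ValueError("concept IRI must be non-empty")


@dataclass
class Ontology:
    id: str
    concepts: dict[str, Concept] = field(default_factory=dict)

    @property
    def concept_count(self) -> int:
        return len(self.concepts)

    @property
    def concept_list(self) -> list[Concept]:
        """Concepts in a stable (insertion) order."""
        return list(self.concepts.values())

    def add(self, concept: Concept) -> None:
        if concept.iri in self.concepts:
            raise OntologyError(f"duplicate concept IRI {concept.iri!r}")
        self.concepts[concept.iri] = concept

    def __contains__(self, iri: str) -> bool:
        return iri in self.concepts


@dataclass(frozen=True)
class ConceptProfile:
    """Multiset of normalized terms for one concept (duplicates retained)."""

    concept_iri: str
    terms: tuple[str, ...]

    @property
    def cardinality(self) -> int:
        return len(self.terms)


def local_fragment(iri: str) -> str:
    """The part of an IRI after '#', or after the last '/'."""
    if "#" in iri:
        return iri.rsplit("#", 1)[1]
    return iri.rstrip("/").rsplit("/", 1)[-1]


_CAMEL_RE = re.compile(r"(?<=[a-z0-9])(?=[A-Z])|(?<=[A-Z])(?=[A-Z][a-z])")
_SPLIT_RE = re.compile(r"[\s_\-]+")
_PUNCT_RE = re.compile(r"[^0-9a-z]+")


def normalize_term(raw: str) -> list[str]:
    """Split a raw string into lowercase word tokens.

    Splits on whitespace, underscores, hyphens and camel-case boundaries,
    strips punctuation, and drops empty tokens. Runs of capitals and
    letter-digit mixes are kept whole ("NCI_C12727" -> ["nci", "c12727"]).
    """
    spaced = _CAMEL_RE.sub(" ", raw)
    tokens = []
    for piece in _SPLIT_RE.split(spaced):
        cleaned = _PUNCT_RE.sub("", piece.lower())
        if cleaned:
            tokens.append(cleaned)
    return tokens


def build_profile(ontology: Ontology, concept: Concept) -> ConceptProfile:
    """Collect the term multiset of a concept and its direct descendants.

    Terms come from labels, comments and property label/domain/range strings
    of the concept plus each direct child. A concept yielding no terms at all
    falls back to its IRI local fragment so profiles are never empty.
    """
    if concept.iri not in ontology.concepts:
        raise ValueError(f"concept {concept.iri!r} not in ontology {ontology.id!r}")
    terms: list[str] = []
    members = [concept]
    for child_iri in concept.direct_descendants:
        child = ontology.concepts.get(child_iri)
        if child is not None:
            members.append(child)
    for member in members:
        for text in member.labels:
            terms.extend(normalize_term(text))
        for text in member.comments:
            terms.extend(normalize_term(text))
        for prop_label, dom_label, range_label in member.property_info:
            terms.extend(normalize_term(prop_label))
            terms.extend(normalize_term(dom_label))
            terms.extend(normalize_term(range_label))
    if not terms:
        terms = normalize_term(local_fragment(concept.iri))
    return ConceptProfile(concept_iri=concept.iri, terms=tuple(terms))


def build_profiles(ontology: Ontology) -> dict[str, ConceptProfile]:
    return {iri: build_profile(ontology, c) for iri, c in ontology.concepts.items()}


# ---------------------------------------------------------------------------
# Triple extraction

Triple = tuple[str, str, str, bool]  # (subject, predicate, object, is_literal)


def _rdfxml_triples(root: ET.Element) -> list[Triple]:
    triples: list[Triple] = []

    def subject_iri(elem: ET.Element) -> str | None:
        about = elem.get(f"{{{RDF_NS}}}about")
        if about is not None:
            return about
        rid = elem.get(f"{{{RDF_NS}}}ID")
        if rid is not None:
            return "#" + rid
        return None

    def walk_node(elem: ET.Element) -> str | None:
        subj = subject_iri(elem)
        if subj is None:
            return None
        if elem.tag != f"{{{RDF_NS}}}Description":
            triples.append((subj, RDF_TYPE, elem.tag.replace("}", "").replace("{", ""), False))
        for pred_elem in elem:
            pred = pred_elem.tag.replace("}", "").replace("{", "")
            resource = pred_elem.get(f"{{{RDF_NS}}}resource")
            if resource is not None:
                triples.append((subj, pred, resource, False))
                continue
            nested = [c for c in pred_elem]
            if nested:
                obj = walk_node(nested[0])
                if obj is not None:
                    triples.append((subj, pred, obj, False))
                continue
            text = (pred_elem.text or "").strip()
            if text:
                triples.append((subj, pred, text, True))
        return subj

    for child in root:
        walk_node(child)
    return triples


_TTL_TOKEN = re.compile(
    r"""
      (?P<comment>\#[^\n]*)
    | (?P<iri><[^>]*>)
    | (?P<literal>"(?:[^"\\]|\\.)*"(?:@[A-Za-z\-]+|\^\^\S+)?)
    | (?P<punct>[;,.\[\]])
    | (?P<word>[^\s;,.\[\]]+)
    """,
    re.VERBOSE,
)


def _tokenize_turtle(text: str) -> list[str]:
    tokens = []
    for m in _TTL_TOKEN.finditer(text):
        if m.lastgroup == "comment":
            continue
        tokens.append(m.group())
    return tokens


def _turtle_triples(text: str) -> list[Triple]:
    """Parse a flat subset of Turtle: prefixed/absolute names, literals,
    'a', predicate lists (';') and object lists (','). Blank nodes are
    tolerated but dropped."""
    prefixes: dict[str, str] = {}
    tokens = _tokenize_turtle(text)
    triples: list[Triple] = []

    def expand(token: str) -> tuple[str, bool]:
        if token.startswith("<") and token.endswith(">"):
            return token[1:-1], False
        if token.startswith('"'):
            body = token
            if body.rfind('"') != len(body) - 1:  # trailing @lang or ^^type
                body = body[: body.rfind('"') + 1]
            return body[1:-1].encode().decode("unicode_escape"), True
        if token == "a":
            return RDF_TYPE, False
        if ":" in token:
            prefix, local = token.split(":", 1)
            if prefix in prefixes:
                return prefixes[prefix] + local, False
        return token, False

    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        if tok in ("@prefix", "PREFIX"):
            prefix = tokens[i + 1].rstrip(":")
            iri, _ = expand(tokens[i + 2])
            prefixes[prefix] = iri
            i += 3
            if i < n and tokens[i] == ".":
                i += 1
            continue
        if tok in ("@base", "BASE"):
            i += 2
            if i < n and tokens[i] == ".":
                i += 1
            continue
        if tok in (".", ";", ",", "[", "]"):
            i += 1
            continue
        subj, subj_is_lit = expand(tok)
        if subj_is_lit:
            i += 1
            continue
        blank_subject = tok.startswith("_:") or tok == "["
        i += 1
        while i < n and tokens[i] != ".":
            pred, _ = expand(tokens[i])
            i += 1
            while i < n:
                obj_tok = tokens[i]
                if obj_tok in ("[", "]"):  # skip blank node objects
                    i += 1
                else:
                    obj, is_lit = expand(obj_tok)
                    if not blank_subject and not obj_tok.startswith("_:"):
                        triples.append((subj, pred, obj, is_lit))
                    i += 1
                if i < n and tokens[i] == ",":
                    i += 1
                    continue
                break
            if i < n and tokens[i] == ";":
                i += 1
                if i < n and tokens[i] == ".":
                    break
            else:
                break
        if i < n and tokens[i] == ".":
            i += 1
    return triples


def _label_of(iri: str, labels: dict[str, list[str]]) -> str:
    found = labels.get(iri)
    if found:
        return found[0]
    return local_fragment(iri)


def _ontology_from_triples(triples: list[Triple], ontology_id: str) -> Ontology:
    types: dict[str, set[str]] = {}
    labels: dict[str, list[str]] = {}
    comments: dict[str, list[str]] = {}
    subclass_of: list[tuple[str, str]] = []
    domains: dict[str, list[str]] = {}
    ranges: dict[str, list[str]] = {}
    for s, p, o, is_lit in triples:
        if p == RDF_TYPE and not is_lit:
            types.setdefault(s, set()).add(o)
        elif p == RDFS_LABEL and is_lit:
            labels.setdefault(s, []).append(o)
        elif p == RDFS_COMMENT and is_lit:
            comments.setdefault(s, []).append(o)
        elif p == RDFS_SUBCLASSOF and not is_lit:
            subclass_of.append((s, o))
        elif p == RDFS_DOMAIN and not is_lit:
            domains.setdefault(s, []).append(o)
        elif p == RDFS_RANGE and not is_lit:
            ranges.setdefault(s, []).append(o)

    class_iris = sorted(iri for iri, ts in types.items() if OWL_CLASS in ts)
    if not class_iris:
        raise OntologyError(f"ontology {ontology_id!r} declares no named classes")

    ontology = Ontology(id=ontology_id)
    for iri in class_iris:
        concept = Concept(
            iri=iri,
            labels=list(labels.get(iri, [])) or [local_fragment(iri)],
            comments=list(comments.get(iri, [])),
        )
        ontology.add(concept)

    for child, parent in subclass_of:
        if child in ontology.concepts and parent in ontology.concepts:
            siblings = ontology.concepts[parent].direct_descendants
            if child not in siblings:
                siblings.append(child)

    for prop_iri, ts in types.items():
        if not (ts & _PROPERTY_TYPES):
            continue
        prop_label = _label_of(prop_iri, labels)
        range_label = ""
        if ranges.get(prop_iri):
            range_label = _label_of(ranges[prop_iri][0], labels)
        for domain_iri in domains.get(prop_iri, []):
            if domain_iri in ontology.concepts:
                ontology.concepts[domain_iri].property_info.append(
                    (prop_label, _label_of(domain_iri, labels), range_label)
                )
    for concept in ontology.concepts.values():
        concept.direct_descendants.sort()
        concept.property_info.sort()
    return ontology


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".ttl", ".n3"):
        return "turtle"
    if suffix in (".owl", ".rdf", ".xml"):
        return "rdfxml"
    head = path.read_text(errors="replace")[:2048].lstrip()
    return "rdfxml" if head.startswith("<") else "turtle"


def load_ontology(path: str | Path, format: str = "auto") -> Ontology:
    """Load an OWL file into the internal model.

    One :class:`Concept` per named class; anonymous (blank-node) classes are
    skipped with a warning; a class with no ``rdfs:label`` uses its IRI local
    fragment as label.
    """
    path = Path(path)
    if format not in ("rdfxml", "turtle", "auto"):
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt == "rdfxml":
        try:
            root = ET.parse(path).getroot()
        except ET.ParseError as exc:
            raise OntologyError(f"cannot parse RDF/XML file {path}: {exc}") from exc
        blank = sum(
            1
            for elem in root.iter(f"{{{OWL_NS}}}Class")
            if elem.get(f"{{{RDF_NS}}}about") is None and elem.get(f"{{{RDF_NS}}}ID") is None
        )
        if blank:
            logger.warning("%s: skipped %d anonymous class node(s)", path.name, blank)
        triples = _rdfxml_triples(root)
    else:
        triples = _turtle_triples(path.read_text())
    return _ontology_from_triples(triples, ontology_id=path.stem)


def write_owl(ontology: Ontology, path: str | Path) -> Path:
    """Serialize the internal model as RDF/XML (labels, comments, subclass
    links, and per-domain property declarations)."""
    path = Path(path)
    ET.register_namespace("rdf", RDF_NS)
    ET.register_namespace("rdfs", RDFS_NS)
    ET.register_namespace("owl", OWL_NS)
    root = ET.Element(f"{{{RDF_NS}}}RDF")
    parent_of: dict[str, str] = {}
    for concept in ontology.concept_list:
        for child in concept.direct_descendants:
            parent_of[child] = concept.iri
    for concept in ontology.concept_list:
        node = ET.SubElement(root, f"{{{OWL_NS}}}Class")
        node.set(f"{{{RDF_NS}}}about", concept.iri)
        for text in concept.labels:
            ET.SubElement(node, f"{{{RDFS_NS}}}label").text = text
        for text in concept.comments:
            ET.SubElement(node, f"{{{RDFS_NS}}}comment").text = text
        if concept.iri in parent_of:
            sub = ET.SubElement(node, f"{{{RDFS_NS}}}subClassOf")
            sub.set(f"{{{RDF_NS}}}resource", parent_of[concept.iri])
    prop_counter = 0
    for concept in ontology.concept_list:
        for prop_label, _domain_label, range_label in concept.property_info:
            prop_counter += 1
            node = ET.SubElement(root, f"{{{OWL_NS}}}ObjectProperty")
            node.set(f"{{{RDF_NS}}}about", f"{concept.iri}.p{prop_counter}")
            ET.SubElement(node, f"{{{RDFS_NS}}}label").text = prop_label
            dom = ET.SubElement(node, f"{{{RDFS_NS}}}domain")
            dom.set(f"{{{RDF_NS}}}resource", concept.iri)
            if range_label:
                # range label is carried in the IRI fragment; the loader's
                # fragment fallback recovers it without declaring a class
                rng = ET.SubElement(node, f"{{{RDFS_NS}}}range")
                rng.set(f"{{{RDF_NS}}}resource", f"urn:range#{range_label.replace(' ', '_')}")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
    return path
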