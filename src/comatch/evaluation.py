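"""Alignment construction, rough metrics, and reference-based scoring.

A decoded solution is turned into an equivalence alignment by keeping, for
each mapped source concept, the correspondence whose cached similarity is at
least the solution's threshold (and nonzero). Alignments are scored with
three reference-free metrics — MatchCoverage (recall surrogate), MatchRatio
(precision surrogate) and their harmonic mean MatchFmeasure — and, when a
reference alignment is available, with traditional precision/recall/f-measure.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from comatch.encoding import DecodedSolution
from comatch.ontology_io import Ontology
from comatch.similarity import SimilarityMatrix

ALIGN_NS = "http://knowledgeweb.semanticweb.org/heterogeneity/alignment"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
XSD_FLOAT = "http://www.w3.org/2001/XMLSchema#float"


@dataclass(frozen=True)
class Correspondence:
    """Equivalence correspondence (e1, e2, n) with confidence n in [0, 1]."""

    source_iri: str
    target_iri: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.confidence <= 1:
            raise ValueError("confidence must be in [0, 1]")


class Alignment:
    """A set of correspondences; each source IRI appears at most once."""

    def __init__(self, correspondences: Iterable[Correspondence] = ()):
        corrs = list(correspondences)
        seen = set()
        for c in corrs:
            if c.source_iri in seen:
                raise ValueError(f"source {c.source_iri!r} appears more than once")
            seen.add(c.source_iri)
        self.correspondences: tuple[Correspondence, ...] = tuple(corrs)

    def __len__(self) -> int:
        return len(self.correspondences)

    def __iter__(self) -> Iterator[Correspondence]:
        return iter(self.correspondences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return set(self.correspondences) == set(other.correspondences)

    def __repr__(self) -> str:
        return f"Alignment({len(self)} correspondences)"

    def pairs(self) -> set[tuple[str, str]]:
        """(source, target) pairs, confidence ignored."""
        return {(c.source_iri, c.target_iri) for c in self.correspondences}

    def source_iris(self) -> set[str]:
        return {c.source_iri for c in self.correspondences}

    def target_iris(self) -> set[str]:
        return {c.target_iri for c in self.correspondences}

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [
            f"{c.source_iri}\t{c.target_iri}\t{c.confidence:.6f}\n"
            for c in self.correspondences
        ]
        path.write_text("".join(lines))
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Alignment":
        corrs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                parts.append("1.0")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
            corrs.append(Correspondence(parts[0], parts[1], float(parts[2])))
        return cls(corrs)

    def to_rdf(self, path: str | Path) -> Path:
        """Write OAEI Alignment format (RDF/XML with Cell elements)."""
        path = Path(path)
        ET.register_namespace("rdf", RDF_NS)
        ET.register_namespace("", ALIGN_NS)
        root = ET.Element(f"{{{RDF_NS}}}RDF")
        align = ET.SubElement(root, f"{{{ALIGN_NS}}}Alignment")
        ET.SubElement(align, f"{{{ALIGN_NS}}}xml").text = "yes"
        ET.SubElement(align, f"{{{ALIGN_NS}}}level").text = "0"
        ET.SubElement(align, f"{{{ALIGN_NS}}}type").text = "11"
        for c in self.correspondences:
            cell_map = ET.SubElement(align, f"{{{ALIGN_NS}}}map")
            cell = ET.SubElement(cell_map, f"{{{ALIGN_NS}}}Cell")
            e1 = ET.SubElement(cell, f"{{{ALIGN_NS}}}entity1")
            e1.set(f"{{{RDF_NS}}}resource", c.source_iri)
            e2 = ET.SubElement(cell, f"{{{ALIGN_NS}}}entity2")
            e2.set(f"{{{RDF_NS}}}resource", c.target_iri)
            measure = ET.SubElement(cell, f"{{{ALIGN_NS}}}measure")
            measure.set(f"{{{RDF_NS}}}datatype", XSD_FLOAT)
            measure.text = f"{c.confidence:.6f}"
            ET.SubElement(cell, f"{{{ALIGN_NS}}}relation").text = "="
        tree = ET.ElementTree(root)
        ET.indent(tree)
        tree.write(path, xml_declaration=True, encoding="unicode")
        return path

    @classmethod
    def from_rdf(cls, path: str | Path) -> "Alignment":
        """Read OAEI Alignment format; matches Cell elements by local name
        so namespace variants parse too."""
        root = ET.parse(Path(path)).getroot()
        corrs = []
        for cell in root.iter():
            if not cell.tag.endswith("}Cell") and cell.tag != "Cell":
                continue
            source = target = None
            confidence = 1.0
            for child in cell:
                local = child.tag.rsplit("}", 1)[-1]
                if local == "entity1":
                    source = child.get(f"{{{RDF_NS}}}resource") or child.get("resource")
                elif local == "entity2":
                    target = child.get(f"{{{RDF_NS}}}resource") or child.get("resource")
                elif local == "measure" and child.text:
                    confidence = float(child.text)
            if source is None or target is None:
                raise ValueError(f"{path}: Cell without entity1/entity2 resources")
            corrs.append(Correspondence(source, target, confidence))
        return cls(corrs)

    @classmethod
    def from_file(cls, path: str | Path) -> "Alignment":
        path = Path(path)
        if path.suffix.lower() in (".tsv", ".txt", ".csv"):
            return cls.from_tsv(path)
        return cls.from_rdf(path)


@dataclass(frozen=True)
class MatchScores:
    """The three reference-free metrics of one candidate alignment."""

    match_coverage: float
    match_ratio: float
    match_fmeasure: float


@dataclass(frozen=True)
class ReferenceScores:
    precision: float
    recall: float
    fmeasure: float


def decode_to_alignment(
    sol: DecodedSolution,
    sim: SimilarityMatrix,
    o1: Ontology,
    o2: Ontology,
) -> Alignment:
    """Filter a decoded solution into an alignment.

    For each source concept i mapped to target j > 0, the correspondence is
    kept iff sim(i, j) >= threshold and sim(i, j) > 0; zero-similarity pairs
    are never emitted (they carry no evidence).
    """
    mapping = np.asarray(sol.mapping)
    if mapping.shape[0] != sim.n1 or sim.n1 != o1.concept_count or sim.n2 != o2.concept_count:
        raise ValueError("solution / similarity matrix / ontology sizes disagree")
    corrs = []
    for i, j in enumerate(mapping):
        if j <= 0:
            continue
        value = float(sim.values[i, j - 1])
        if value >= sol.threshold and value > 0:
            corrs.append(
                Correspondence(sim.source_iris[i], sim.target_iris[j - 1], value)
            )
    return Alignment(corrs)


def match_coverage(a: Alignment, o1: Ontology, o2: Ontology) -> float:
    """Fraction of all concepts (both ontologies) present in at least one
    correspondence."""
    total = o1.concept_count + o2.concept_count
    if total == 0:
        raise ValueError("match_coverage is undefined for empty ontologies")
    return (len(a.source_iris()) + len(a.target_iris())) / total


def match_ratio(a: Alignment) -> float:
    """Distinct matched concepts over twice the correspondence count; 0 for
    an empty alignment. Equals 1 exactly when the alignment is one-to-one."""
    if len(a) == 0:
        return 0.0
    return (len(a.source_iris()) + len(a.target_iris())) / (2 * len(a))


def match_fmeasure(coverage: float, ratio: float) -> float:
    """Harmonic mean of coverage and ratio; 0 when both are 0."""
    if coverage + ratio == 0:
        return 0.0
    return 2 * coverage * ratio / (coverage + ratio)


def match_scores(a: Alignment, o1: Ontology, o2: Ontology) -> MatchScores:
    coverage = match_coverage(a, o1, o2)
    ratio = match_ratio(a)
    return MatchScores(coverage, ratio, match_fmeasure(coverage, ratio))


def solution_scores(
    mapping: np.ndarray, threshold: float, values: np.ndarray
) -> MatchScores:
    """Vectorized rough scores of a decoded solution against a similarity
    array; agrees with the Alignment object path (the EA hot loop uses this)."""
    n1, n2 = values.shape
    mapping = np.asarray(mapping)
    idx = np.nonzero(mapping)[0]
    cols = mapping[idx] - 1
    sims = values[idx, cols]
    keep = (sims >= threshold) & (sims > 0)
    kept_cols = cols[keep]
    n_corr = int(kept_cols.size)
    if n_corr == 0:
        return MatchScores(0.0, 0.0, 0.0)
    distinct_sources = n_corr  # one segment per source concept
    distinct_targets = int(np.unique(kept_cols).size)
    coverage = (distinct_sources + distinct_targets) / (n1 + n2)
    ratio = (distinct_sources + distinct_targets) / (2 * n_corr)
    return MatchScores(coverage, ratio, match_fmeasure(coverage, ratio))


def reference_scores(a: Alignment, ref: Alignment) -> ReferenceScores:
    """Traditional precision/recall/f-measure against a reference alignment.

    Correspondence identity is the (source, target) pair; confidence is
    ignored. An empty candidate alignment has precision 1 by convention.
    """
    if len(ref) == 0:
        raise ValueError("reference_scores is undefined for an empty reference")
    overlap = len(a.pairs() & ref.pairs())
    precision = overlap / len(a) if len(a) else 1.0
    recall = overlap / len(ref)
    if precision + recall == 0:
        fmeasure = 0.0
    else:
        fmeasure = 2 * precision * recall / (precision + recall)
    return ReferenceScores(precision, recall, fmeasure)
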