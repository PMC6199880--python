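"""Synthetic ontology pairs with known ground-truth alignments.

Generates a random tree-shaped ontology with multi-word pseudo-word labels,
then derives a second ontology by copying it and perturbing labels: a
fraction of concepts get every label word replaced by a generated synonym
(recorded in a synonym table), a disjoint fraction get one character of one
word substituted, and a fraction of concepts are dropped. The surviving
identity mapping is returned as the reference alignment, so the ground truth
is one-to-one by construction.

Labels are pronounceable pseudo-words with globally unique words; with all
perturbation fractions at 0 every ground-truth pair has profile similarity
1.0, while word-level n-gram similarity still behaves realistically under
character noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from comatch.evaluation import Alignment, Correspondence
from comatch.ontology_io import Concept, Ontology, write_owl
from comatch.similarity import SynonymProvider

SOURCE_BASE = "http://example.org/source#"
TARGET_BASE = "http://example.org/target#"

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class FixtureSpec:
    n_concepts: int
    branching_factor: int = 3
    synonym_rename_fraction: float = 0.0
    char_noise_fraction: float = 0.0
    dropout_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        if self.branching_factor < 1:
            raise ValueError("branching_factor must be >= 1")
        for name in ("synonym_rename_fraction", "char_noise_fraction", "dropout_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


class _WordPool:
    """Unique pronounceable pseudo-words (CV syllables, optional coda)."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._seen: set[str] = set()

    def word(self) -> str:
        for _ in range(10_000):
            n_syllables = int(self._rng.integers(2, 4))
            chars = []
            for _ in range(n_syllables):
                chars.append(_CONSONANTS[self._rng.integers(len(_CONSONANTS))])
                chars.append(_VOWELS[self._rng.integers(len(_VOWELS))])
            if self._rng.random() < 0.4:
                chars.append(_CONSONANTS[self._rng.integers(len(_CONSONANTS))])
            candidate = "".join(chars)
            if candidate not in self._seen:
                self._seen.add(candidate)
                return candidate
        raise RuntimeError("word pool exhausted")


def _noise_word(word: str, rng: np.random.Generator) -> str:
    """Substitute one interior character, keeping length and lowercase."""
    pos = int(rng.integers(1, len(word))) if len(word) > 1 else 0
    alphabet = _CONSONANTS + _VOWELS
    replacement = word[pos]
    while replacement == word[pos]:
        replacement = alphabet[rng.integers(len(alphabet))]
    return word[:pos] + replacement + word[pos + 1 :]


def _fraction_count(fraction: float, n: int) -> int:
    return int(round(fraction * n))


def generate_pair(
    spec: FixtureSpec,
) -> tuple[Ontology, Ontology, Alignment, SynonymProvider]:
    """Build (source ontology, target ontology, reference, synonym table)."""
    rng = np.random.default_rng(spec.seed)
    pool = _WordPool(rng)
    n = spec.n_concepts

    # random tree: parent drawn among nodes with spare branching capacity
    parent: list[int | None] = [None]
    children_count = [0] * n
    for i in range(1, n):
        open_nodes = [k for k in range(i) if children_count[k] < spec.branching_factor]
        chosen = int(open_nodes[rng.integers(len(open_nodes))]) if open_nodes else 0
        parent.append(chosen)
        children_count[chosen] += 1

    labels = []
    for _ in range(n):
        n_words = int(rng.integers(2, 4))
        labels.append([pool.word() for _ in range(n_words)])

    def build_ontology(base: str, ont_id: str, label_words: list[list[str]], keep: list[int]) -> Ontology:
        keep_set = set(keep)

        def surviving_parent(i: int) -> int | None:
            p = parent[i]
            while p is not None and p not in keep_set:
                p = parent[p]
            return p

        ontology = Ontology(id=ont_id)
        concepts = {}
        for i in keep:
            concept = Concept(
                iri=f"{base}C{i:04d}",
                labels=[" ".join(w.capitalize() for w in label_words[i])],
            )
            concepts[i] = concept
            ontology.add(concept)
        for i in keep:
            p = surviving_parent(i)
            if p is not None:
                concepts[p].direct_descendants.append(concepts[i].iri)
        for concept in ontology.concepts.values():
            concept.direct_descendants.sort()
        return ontology

    o1 = build_ontology(SOURCE_BASE, "source", labels, list(range(n)))

    # target-side perturbations: rename and noise sets are disjoint
    order = rng.permutation(n)
    n_renamed = _fraction_count(spec.synonym_rename_fraction, n)
    n_noisy = _fraction_count(spec.char_noise_fraction, n)
    renamed = set(order[:n_renamed].tolist())
    noisy = set(order[n_renamed : n_renamed + n_noisy].tolist())

    synonyms = SynonymProvider()
    target_labels = []
    for i in range(n):
        words = list(labels[i])
        if i in renamed:
            replaced = []
            for word in words:
                synonym = pool.word()
                synonyms.add(word, synonym)
                replaced.append(synonym)
            words = replaced
        elif i in noisy:
            pos = int(rng.integers(len(words)))
            words[pos] = _noise_word(words[pos], rng)
        target_labels.append(words)

    n_dropped = _fraction_count(spec.dropout_fraction, n)
    droppable = [i for i in range(n) if i != 0]
    dropped = set(
        (np.array(droppable)[rng.permutation(len(droppable))[:n_dropped]]).tolist()
    ) if n_dropped else set()
    survivors = [i for i in range(n) if i not in dropped]

    o2 = build_ontology(TARGET_BASE, "target", target_labels, survivors)

    reference = Alignment(
        Correspondence(f"{SOURCE_BASE}C{i:04d}", f"{TARGET_BASE}C{i:04d}", 1.0)
        for i in survivors
    )
    return o1, o2, reference, synonyms


def write_fixture(
    pair: tuple[Ontology, Ontology, Alignment, SynonymProvider],
    directory: str | Path,
) -> dict[str, Path]:
    """Write the pair as OWL (RDF/XML), reference alignment (OAEI RDF and
    TSV), and the synonym table (TSV)."""
    o1, o2, reference, synonyms = pair
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "source": write_owl(o1, directory / "source.owl"),
        "target": write_owl(o2, directory / "target.owl"),
        "reference_rdf": reference.to_rdf(directory / "reference.rdf"),
        "reference_tsv": reference.to_tsv(directory / "reference.tsv"),
        "synonyms": synonyms.to_file(directory / "synonyms.tsv"),
    }
    return paths
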