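"""Word-, profile- and concept-level similarity.

A concept pair is scored through its profiles p1, p2: with I the number of
identical elements (one-to-one, synonym-aware), the two asymmetric measures
s1 = I/|p1| and s2 = I/|p2| are averaged when they agree to within ``delta``
and the pair scores 0 otherwise. Word identity is 1 for dictionary synonyms,
else a padded-trigram Dice coefficient.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from comatch.ontology_io import ConceptProfile, Ontology, build_profiles

#: key type for the shared word-pair similarity cache
_WordPair = tuple[str, str]


class SynonymProvider:
    """Symmetric, reflexive word-synonymy lookup backed by a flat pair list.

    Stand-in for a terminology service: two normalized words are synonymous
    iff they are equal or their (unordered) pair is listed.
    """

    def __init__(self, pairs: "list[tuple[str, str]] | None" = None):
        self._pairs: set[frozenset[str]] = set()
        for a, b in pairs or []:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a != b:
            self._pairs.add(frozenset((a, b)))

    def are_synonyms(self, a: str, b: str) -> bool:
        return a == b or frozenset((a, b)) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_file(cls, path: str | Path) -> "SynonymProvider":
        """Read a two-column tab-separated file of normalized word pairs."""
        provider = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated words")
            provider.add(parts[0].strip(), parts[1].strip())
        return provider

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = sorted(tuple(sorted(p)) for p in self._pairs)
        path.write_text("".join(f"{a}\t{b}\n" for a, b in lines))
        return path


@dataclass(frozen=True)
class SimilarityParams:
    #: gate on |s1 - s2|; suggested domain [0.01, 0.10], default 0.06
    delta: float = 0.06
    #: strict lower bound for two profile elements to count as identical
    element_match_threshold: float = 0.9
    ngram_size: int = 3

    def __post_init__(self) -> None:
        if self.ngram_size < 1:
            raise ValueError("ngram_size must be >= 1")
        if not 0 <= self.element_match_threshold <= 1:
            raise ValueError("element_match_threshold must be in [0, 1]")


@dataclass
class SimilarityMatrix:
    """Pairwise concept similarities, dense array plus sparse view.

    Row ``i`` / column ``j`` follow the source/target ontologies' stable
    concept order (0-based); absent entries mean similarity 0.
    """

    source_iris: list[str]
    target_iris: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.source_iris), len(self.target_iris)):
            raise ValueError("similarity matrix shape mismatch")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("similarity values must lie in [0, 1]")

    @property
    def n1(self) -> int:
        return len(self.source_iris)

    @property
    def n2(self) -> int:
        return len(self.target_iris)

    @property
    def entries(self) -> dict[tuple[int, int], float]:
        """Sparse map of the nonzero entries."""
        rows, cols = np.nonzero(self.values)
        return {
            (int(i), int(j)): float(self.values[i, j]) for i, j in zip(rows, cols)
        }


_PAD_CHAR = "\x01"


def ngram_similarity(w1: str, w2: str, n: int = 3) -> float:
    """Dice coefficient over padded character n-grams.

    Each word is framed by ``n - 1`` boundary markers on both sides, so words
    shorter than ``n`` still contribute grams. Identical words score 1,
    words sharing no gram score 0; symmetric.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if w1 == w2:
        return 1.0
    pad = _PAD_CHAR * (n - 1)
    p1, p2 = pad + w1 + pad, pad + w2 + pad
    g1 = Counter(p1[i : i + n] for i in range(len(p1) - n + 1))
    g2 = Counter(p2[i : i + n] for i in range(len(p2) - n + 1))
    shared = sum((g1 & g2).values())
    return 2.0 * shared / (sum(g1.values()) + sum(g2.values()))


def word_similarity(
    w1: str,
    w2: str,
    syn: SynonymProvider,
    params: SimilarityParams,
    _cache: "dict[_WordPair, float] | None" = None,
) -> float:
    """1 for synonymous words, otherwise the n-gram similarity."""
    if _cache is not None:
        key = (w1, w2) if w1 <= w2 else (w2, w1)
        hit = _cache.get(key)
        if hit is not None:
            return hit
    value = 1.0 if syn.are_synonyms(w1, w2) else ngram_similarity(w1, w2, params.ngram_size)
    if _cache is not None:
        _cache[key] = value
    return value


def profile_intersection_size(
    p1: ConceptProfile,
    p2: ConceptProfile,
    syn: SynonymProvider,
    params: SimilarityParams,
    _cache: "dict[_WordPair, float] | None" = None,
) -> int:
    """Number of identical elements between two profiles.

    Elements count as identical when their word similarity strictly exceeds
    ``element_match_threshold``. Pairing is a greedy one-to-one matching in
    descending similarity order with lexicographic tie-breaking, so each
    element is consumed at most once; the result is <= min(|p1|, |p2|).
    """
    c1 = Counter(p1.terms)
    c2 = Counter(p2.terms)
    scored: list[tuple[float, str, str]] = []
    for w1 in c1:
        for w2 in c2:
            s = word_similarity(w1, w2, syn, params, _cache)
            if s > params.element_match_threshold:
                scored.append((s, w1, w2))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched = 0
    for _, w1, w2 in scored:
        take = min(c1[w1], c2[w2])
        if take:
            matched += take
            c1[w1] -= take
            c2[w2] -= take
    return matched


def profile_similarity(
    p1: ConceptProfile,
    p2: ConceptProfile,
    syn: SynonymProvider,
    params: SimilarityParams,
    _cache: "dict[_WordPair, float] | None" = None,
) -> float:
    """Delta-gated average of the two asymmetric profile measures."""
    if p1.cardinality == 0 or p2.cardinality == 0:
        raise ValueError("profile similarity is undefined for empty profiles")
    inter = profile_intersection_size(p1, p2, syn, params, _cache)
    s1 = inter / p1.cardinality
    s2 = inter / p2.cardinality
    if abs(s1 - s2) > params.delta:
        return 0.0
    return (s1 + s2) / 2.0


def similarity_matrix(
    o1: Ontology,
    o2: Ontology,
    syn: SynonymProvider,
    params: SimilarityParams,
) -> SimilarityMatrix:
    """All-pairs profile similarity between two loaded ontologies.

    Profiles are built once per ontology and word-pair similarities are
    cached across concept pairs; downstream fitness evaluation only reads
    the resulting matrix and never re-tokenizes.
    """
    profiles1 = build_profiles(o1)
    profiles2 = build_profiles(o2)
    source_iris = [c.iri for c in o1.concept_list]
    target_iris = [c.iri for c in o2.concept_list]
    values = np.zeros((len(source_iris), len(target_iris)))
    cache: dict[_WordPair, float] = {}
    for i, iri1 in enumerate(source_iris):
        p1 = profiles1[iri1]
        for j, iri2 in enumerate(target_iris):
            values[i, j] = profile_similarity(p1, profiles2[iri2], syn, params, cache)
    return SimilarityMatrix(source_iris=source_iris, target_iris=target_iris, values=values)
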