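import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comatch.ontology_io import ConceptProfile
from comatch.similarity import (
    SimilarityParams,
    SynonymProvider,
    ngram_similarity,
    profile_intersection_size,
    profile_similarity,
    similarity_matrix,
    word_similarity,
)
from comatch.synthetic_fixtures import FixtureSpec, generate_pair


def profile(*terms):
    return ConceptProfile(concept_iri="urn:p", terms=tuple(terms))


def oracle_ngram(w1, w2, n):
    """Independent brute-force padded-gram Dice enumeration."""
    pad = "\x01" * (n - 1)
    a, b = pad + w1 + pad, pad + w2 + pad
    g1 = [a[i : i + n] for i in range(len(a) - n + 1)]
    g2 = [b[i : i + n] for i in range(len(b) - n + 1)]
    shared = 0
    remaining = list(g2)
    for gram in g1:
        if gram in remaining:
            remaining.remove(gram)
            shared += 1
    return 2 * shared / (len(g1) + len(g2))


def oracle_intersection(p1, p2, syn, params):
    """Exhaustive maximum one-to-one matching over all pair subsets."""
    e1, e2 = list(p1.terms), list(p2.terms)
    if len(e1) > len(e2):
        e1, e2 = e2, e1
    best = 0
    for perm in itertools.permutations(range(len(e2)), len(e1)):
        count = sum(
            1
            for i, j in enumerate(perm)
            if word_similarity(e1[i], e2[j], syn, params) > params.element_match_threshold
        )
        best = max(best, count)
    return best


class TestNgram:
    def test_identity(self):
        assert ngram_similarity("myocardium", "myocardium", 3) == 1.0

    def test_no_shared_trigram(self):
        assert ngram_similarity("abc", "xyz", 3) == 0.0

    def test_myocardium_myocardial_matches_enumeration(self):
        # shared padded trigrams enumerated by hand: 8 of 12 per side
        assert ngram_similarity("myocardium", "myocardial", 3) == pytest.approx(2 / 3)
        assert oracle_ngram("myocardium", "myocardial", 3) == pytest.approx(2 / 3)

    def test_short_words_padded_not_error(self):
        assert 0 < ngram_similarity("ab", "ab2", 3) < 1

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            ngram_similarity("a", "b", 0)

    @given(
        st.text(alphabet="abcdefg", min_size=1, max_size=8),
        st.text(alphabet="abcdefg", min_size=1, max_size=8),
        st.integers(min_value=1, max_value=4),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_bounded_and_matches_oracle(self, w1, w2, n):
        value = ngram_similarity(w1, w2, n)
        assert value == ngram_similarity(w2, w1, n)
        assert 0 <= value <= 1
        assert value == pytest.approx(oracle_ngram(w1, w2, n))


class TestWordSimilarity:
    def test_synonyms_score_one(self, sim_params):
        syn = SynonymProvider([("myocardium", "cardiac")])
        assert word_similarity("myocardium", "cardiac", syn, sim_params) == 1.0

    def test_identity_without_synonyms(self, empty_syn, sim_params):
        assert word_similarity("heart", "heart", empty_syn, sim_params) == 1.0

    def test_unrelated_words(self, empty_syn, sim_params):
        assert word_similarity("abc", "xyz", empty_syn, sim_params) == 0.0

    def test_provider_symmetric_reflexive(self):
        syn = SynonymProvider([("a", "b")])
        assert syn.are_synonyms("a", "b") and syn.are_synonyms("b", "a")
        assert syn.are_synonyms("zzz", "zzz")

    def test_provider_file_round_trip(self, tmp_path):
        syn = SynonymProvider([("alpha", "beta"), ("gamma", "delta")])
        path = syn.to_file(tmp_path / "syn.tsv")
        loaded = SynonymProvider.from_file(path)
        assert loaded.are_synonyms("alpha", "beta")
        assert loaded.are_synonyms("delta", "gamma")
        assert len(loaded) == 2

    def test_provider_rejects_malformed_line(self, tmp_path):
        path = tmp_path / "syn.tsv"
        path.write_text("only-one-column\n")
        with pytest.raises(ValueError):
            SynonymProvider.from_file(path)


class TestProfileIntersection:
    def test_identical_profiles(self, empty_syn, sim_params):
        p = profile("a1", "b2", "c3", "d4")
        assert profile_intersection_size(p, p, empty_syn, sim_params) == 4

    def test_disjoint_profiles(self, empty_syn, sim_params):
        p1 = profile("abc", "def")
        p2 = profile("xyz", "uvw")
        assert profile_intersection_size(p1, p2, empty_syn, sim_params) == 0

    def test_synonym_bridge(self, sim_params):
        syn = SynonymProvider([("cardiac", "myocardium")])
        p1 = profile("cardiac", "muscle", "tissue")
        p2 = profile("myocardium", "wall")
        assert profile_intersection_size(p1, p2, syn, sim_params) == 1
        assert oracle_intersection(p1, p2, syn, sim_params) == 1

    def test_bounded_by_smaller_profile(self, empty_syn, sim_params):
        p1 = profile("a1", "a1", "a1")
        p2 = profile("a1")
        assert profile_intersection_size(p1, p2, empty_syn, sim_params) == 1

    @given(
        st.lists(st.sampled_from(["alpha", "beta", "gamma", "alphq"]), min_size=1, max_size=4),
        st.lists(st.sampled_from(["alpha", "beta", "gamma", "alphq"]), min_size=1, max_size=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_greedy_equals_exhaustive_oracle(self, terms1, terms2):
        syn = SynonymProvider([("beta", "gamma")])
        params = SimilarityParams()
        p1, p2 = profile(*terms1), profile(*terms2)
        assert profile_intersection_size(p1, p2, syn, params) == oracle_intersection(
            p1, p2, syn, params
        )


class TestProfileSimilarity:
    def test_identical_profiles(self, empty_syn, sim_params):
        p = profile("a1", "b2", "c3", "d4")
        assert profile_similarity(p, p, empty_syn, sim_params) == 1.0

    def test_gated_to_zero(self, empty_syn, sim_params):
        # |p1|=4, |p2|=5, I=2: s1=0.5, s2=0.4, gap 0.1 > delta 0.06
        p1 = profile("a1", "b2", "x1", "x2")
        p2 = profile("a1", "b2", "y1", "y2", "y3")
        assert profile_similarity(p1, p2, empty_syn, sim_params) == 0.0

    def test_equal_sizes_average(self, empty_syn, sim_params):
        # |p1|=|p2|=4, I=3 -> (0.75 + 0.75)/2
        p1 = profile("a1", "b2", "c3", "x1")
        p2 = profile("a1", "b2", "c3", "y1")
        assert profile_similarity(p1, p2, empty_syn, sim_params) == pytest.approx(0.75)

    def test_empty_profile_rejected(self, empty_syn, sim_params):
        with pytest.raises(ValueError):
            profile_similarity(profile(), profile("a1"), empty_syn, sim_params)

    @given(
        st.lists(st.sampled_from(["aaa", "bbb", "ccc", "ddd"]), min_size=1, max_size=5),
        st.lists(st.sampled_from(["aaa", "bbb", "ccc", "ddd"]), min_size=1, max_size=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_gate_respected(self, terms1, terms2):
        syn, params = SynonymProvider(), SimilarityParams()
        p1, p2 = profile(*terms1), profile(*terms2)
        value = profile_similarity(p1, p2, syn, params)
        assert value == profile_similarity(p2, p1, syn, params)
        if value > 0:
            inter = profile_intersection_size(p1, p2, syn, params)
            s1, s2 = inter / p1.cardinality, inter / p2.cardinality
            assert abs(s1 - s2) <= params.delta
            assert value == pytest.approx((s1 + s2) / 2)

    def test_monotone_in_synonym_relation(self, sim_params):
        p1 = profile("cardiac", "muscle")
        p2 = profile("myocardium", "muscle")
        small = SynonymProvider()
        large = SynonymProvider([("cardiac", "myocardium")])
        assert profile_similarity(p1, p2, large, sim_params) >= profile_similarity(
            p1, p2, small, sim_params
        )


class TestSimilarityMatrix:
    def test_self_similarity_diagonal(self, empty_syn, sim_params):
        o1, o2, _, _ = generate_pair(FixtureSpec(n_concepts=3, seed=1))
        matrix = similarity_matrix(o1, o2, empty_syn, sim_params)
        assert np.allclose(np.diag(matrix.values), 1.0)

    def test_agrees_with_double_loop(self, sim_params):
        from comatch.ontology_io import build_profiles

        o1, o2, _, syn = generate_pair(
            FixtureSpec(n_concepts=8, seed=5, synonym_rename_fraction=0.25)
        )
        matrix = similarity_matrix(o1, o2, syn, sim_params)
        profiles1, profiles2 = build_profiles(o1), build_profiles(o2)
        for i, c1 in enumerate(o1.concept_list):
            for j, c2 in enumerate(o2.concept_list):
                expected = profile_similarity(
                    profiles1[c1.iri], profiles2[c2.iri], syn, sim_params
                )
                assert matrix.values[i, j] == pytest.approx(expected)

    def test_transpose_symmetry(self, empty_syn, sim_params):
        o1, o2, _, _ = generate_pair(FixtureSpec(n_concepts=6, seed=2, char_noise_fraction=0.3))
        forward = similarity_matrix(o1, o2, empty_syn, sim_params)
        backward = similarity_matrix(o2, o1, empty_syn, sim_params)
        assert np.allclose(forward.values, backward.values.T)

    def test_entries_sparse_view(self, empty_syn, sim_params):
        o1, o2, _, _ = generate_pair(FixtureSpec(n_concepts=4, seed=1))
        matrix = similarity_matrix(o1, o2, empty_syn, sim_params)
        entries = matrix.entries
        assert all(0 < v <= 1 for v in entries.values())
        dense = np.zeros_like(matrix.values)
        for (i, j), v in entries.items():
            dense[i, j] = v
        assert np.allclose(dense, matrix.values)
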