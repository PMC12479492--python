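import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon as scipy_js

from corpus_fidelity import (
    average_bigram_pmi,
    bigrams,
    corpus_profile,
    distribution,
    document_profile,
    jensen_shannon_divergence,
    shannon_entropy,
)
from conftest import make_corpus, make_doc

counts_strategy = st.dictionaries(
    st.sampled_from(list("abcdefgh")), st.integers(1, 20), min_size=1, max_size=8
)


def brute_force_avg_pmi(tokens: list[str], min_freq: int) -> float | None:
    """Independent counting oracle: literal definition on the raw stream."""
    pairs = list(zip(tokens, tokens[1:]))
    if not pairs:
        return None
    n = len(pairs)
    vals = []
    for pair in sorted(set(pairs)):
        c = pairs.count(pair)
        if c < min_freq:
            continue
        pa = tokens.count(pair[0]) / len(tokens)
        pb = tokens.count(pair[1]) / len(tokens)
        vals.append(math.log2((c / n) / (pa * pb)))
    return sum(vals) / len(vals) if vals else None


def kl_based_jsd(p: dict, q: dict) -> float:
    """Independent oracle: JSD = 1/2 KL(P||M) + 1/2 KL(Q||M)."""
    support = set(p) | set(q)
    m = {t: (p.get(t, 0.0) + q.get(t, 0.0)) / 2 for t in support}
    kl_pm = sum(pp * math.log2(pp / m[t]) for t, pp in p.items() if pp > 0)
    kl_qm = sum(qq * math.log2(qq / m[t]) for t, qq in q.items() if qq > 0)
    return 0.5 * kl_pm + 0.5 * kl_qm


class TestShannonEntropy:
    def test_closed_forms(self):
        assert shannon_entropy(distribution(["a", "b"])) == pytest.approx(1.0)
        assert shannon_entropy(distribution(["a", "a", "a"])) == 0.0
        assert shannon_entropy(distribution(["a", "a", "b", "c"])) == pytest.approx(1.5)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(counts_strategy)
    def test_bounds_and_relabeling_invariance(self, counts):
        from corpus_fidelity import TokenDistribution

        d = TokenDistribution.from_counts(counts)
        h = shannon_entropy(d)
        assert -1e-12 <= h <= math.log2(d.support_size) + 1e-12
        relabeled = TokenDistribution.from_counts(
            {t.upper() + "_x": c for t, c in counts.items()}
        )
        assert shannon_entropy(relabeled) == pytest.approx(h)


class TestJensenShannon:
    def test_identity_and_disjoint(self):
        p = distribution(["a", "b", "a"])
        assert jensen_shannon_divergence(p, p) == 0.0
        assert jensen_shannon_divergence(
            distribution(["a"]), distribution(["b"])
        ) == pytest.approx(1.0)

    def test_known_value_against_kl_oracle(self):
        p = distribution(["a", "a"])
        q = distribution(["a", "b"])
        expected = kl_based_jsd(p.probs, q.probs)
        assert expected == pytest.approx(0.311278, abs=1e-6)
        assert jensen_shannon_divergence(p, q) == pytest.approx(expected, abs=1e-12)

    def test_sqrt_option_gives_metric_distance(self):
        p = distribution(["a", "a"])
        q = distribution(["a", "b"])
        jsd = jensen_shannon_divergence(p, q)
        assert jensen_shannon_divergence(p, q, sqrt=True) == pytest.approx(math.sqrt(jsd))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(counts_strategy, counts_strategy)
    def test_symmetric_bounded_and_matches_scipy(self, c1, c2):
        from corpus_fidelity import TokenDistribution

        P = TokenDistribution.from_counts(c1)
        Q = TokenDistribution.from_counts(c2)
        jsd = jensen_shannon_divergence(P, Q)
        assert 0.0 <= jsd <= 1.0
        assert jsd == pytest.approx(jensen_shannon_divergence(Q, P), abs=1e-12)
        support = sorted(set(c1) | set(c2))
        p = np.array([P.p(t) for t in support])
        q = np.array([Q.p(t) for t in support])
        assert jsd == pytest.approx(float(scipy_js(p, q, base=2) ** 2), abs=1e-9)


class TestAverageBigramPmi:
    def test_constant_stream_is_zero(self):
        tokens = ["a"] * 4
        assert average_bigram_pmi(distribution(tokens), bigrams(tokens), 1) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "min_freq,expected",
        [(3, (math.log2(16 / 7) + math.log2(12 / 7)) / 2), (4, math.log2(16 / 7))],
    )
    def test_alternating_stream_hand_count(self, min_freq, expected):
        tokens = ["a", "b"] * 4
        got = average_bigram_pmi(distribution(tokens), bigrams(tokens), min_freq)
        assert got == pytest.approx(expected, abs=1e-5)
        assert got == pytest.approx(brute_force_avg_pmi(tokens, min_freq), abs=1e-12)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from("abcd"), min_size=2, max_size=40), st.integers(1, 4))
    def test_matches_brute_force_oracle_on_fuzzed_streams(self, tokens, min_freq):
        got = average_bigram_pmi(distribution(tokens), bigrams(tokens), min_freq)
        expected = brute_force_avg_pmi(tokens, min_freq)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from("abc"), min_size=2, max_size=40))
    def test_raising_min_freq_never_adds_qualifying_bigrams(self, tokens):
        table = bigrams(tokens)
        counts = [sum(1 for c in table.counts.values() if c >= f) for f in (1, 2, 3)]
        assert counts == sorted(counts, reverse=True)

    def test_inconsistent_inputs_error(self):
        from corpus_fidelity.text_units import BigramTable

        uni = distribution(["a", "a"])
        bad = BigramTable(counts={("a", "z"): 1}, total_bigrams=1)
        with pytest.raises(ValueError, match="unigram"):
            average_bigram_pmi(uni, bad, 1)


class TestProfiles:
    def test_document_profile_basics(self):
        doc = make_doc("d1", "a b a b")
        pool = distribution(["a", "b", "a", "b"])
        prof = document_profile(doc, pool, 1)
        assert prof.jsd_vs_pool == 0.0
        assert prof.word_count == 4
        assert prof.unique_word_count == 2

    def test_char_entropy_two_equifrequent_chars(self):
        doc = make_doc("d1", "aabb")
        prof = document_profile(doc, distribution(["aabb"]), 1)
        assert prof.char_entropy_bits == pytest.approx(1.0)

    def test_empty_document_names_offender(self):
        doc = make_doc("leeg", "...")
        with pytest.raises(ValueError, match="leeg"):
            document_profile(doc, distribution(["a"]), 1)

    def test_pooled_entropy_on_concatenated_counts(self):
        same = make_corpus("c", {"d1": "a", "d2": "a"})
        assert corpus_profile(same).pooled_word_entropy_bits == 0.0
        two = make_corpus("c", {"d1": "a", "d2": "b"})
        assert corpus_profile(two).pooled_word_entropy_bits == pytest.approx(1.0)

    def test_single_doc_pooled_equals_doc_entropy(self):
        corpus = make_corpus("c", {"d1": "a b c a"})
        prof = corpus_profile(corpus)
        assert prof.pooled_word_entropy_bits == pytest.approx(
            prof.per_doc_profiles[0].word_entropy_bits
        )
        assert prof.mean_doc_length_chars == prof.per_doc_profiles[0].char_length

    def test_unique_never_exceeds_word_count(self, two_small_corpora):
        ref, _ = two_small_corpora
        for p in corpus_profile(ref).per_doc_profiles:
            assert p.unique_word_count <= p.word_count
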