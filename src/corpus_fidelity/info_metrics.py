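"""Information-theoretic text metrics: Shannon entropy, Jensen-Shannon
divergence and average bigram pointwise mutual information, plus the
per-document and corpus profiles built from them.

All logarithms are base 2: entropies are in bits, and the Jensen-Shannon
divergence is then naturally bounded in [0, 1] (0 for identical
distributions, 1 for disjoint supports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .corpus_io import Corpus, Document
from .text_units import (
    BigramTable,
    TokenDistribution,
    bigrams,
    char_sequence,
    distribution,
    pooled_bigrams,
    pooled_distribution,
    tokenize_words,
)


def shannon_entropy(dist: TokenDistribution) -> float:
    """H = -sum p log2 p, in bits.

    Zero iff the distribution is concentrated on a single token; at most
    log2(support size).
    """
    return -sum(p * math.log2(p) for p in dist.probs.values())


def jensen_shannon_divergence(
    P: TokenDistribution, Q: TokenDistribution, *, sqrt: bool = False
) -> float:
    """Canonical Jensen-Shannon divergence between two token distributions.

    JSD = H(M) - (H(P) + H(Q))/2 with M = (P+Q)/2 over the union support,
    base 2.  Symmetric, 0 iff P == Q, 1 iff the supports are disjoint.
    With ``sqrt=True`` returns the Jensen-Shannon distance (the metric).
    """
    p, q = P.probs, Q.probs
    support = set(p) | set(q)
    h_m = 0.0
    for t in support:
        m = (p.get(t, 0.0) + q.get(t, 0.0)) / 2.0
        h_m -= m * math.log2(m)
    jsd = h_m - (shannon_entropy(P) + shannon_entropy(Q)) / 2.0
    jsd = min(max(jsd, 0.0), 1.0)  # clamp fp residue at the bounds
    return math.sqrt(jsd) if sqrt else jsd


def average_bigram_pmi(
    unigrams: TokenDistribution,
    bigram_table: BigramTable,
    min_freq: int = 1,
    *,
    weighted: bool = False,
) -> Optional[float]:
    """Mean PMI over bigram types with count >= ``min_freq``, in bits.

    PMI(a, b) = log2[ (c(a,b)/N) / (p(a) p(b)) ] with N the total number of
    bigram tokens.  By default the mean is unweighted over qualifying bigram
    TYPES; ``weighted=True`` weights each type by its count.  Returns None
    when no bigram qualifies.
    """
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    if bigram_table.total_bigrams == 0:
        return None
    n = bigram_table.total_bigrams
    pmis = []
    weights = []
    for (a, b), c in bigram_table.counts.items():
        if c < min_freq:
            continue
        pa, pb = unigrams.p(a), unigrams.p(b)
        if pa == 0.0 or pb == 0.0:
            raise ValueError(f"bigram token not present in unigram distribution: {(a, b)}")
        pmis.append(math.log2((c / n) / (pa * pb)))
        weights.append(c)
    if not pmis:
        return None
    if weighted:
        return sum(p * w for p, w in zip(pmis, weights)) / sum(weights)
    return sum(pmis) / len(pmis)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DocProfile:
    """The eight per-document features used for document-level assessment."""

    size_mb: float
    word_count: int
    unique_word_count: int
    char_length: int
    char_entropy_bits: float
    word_entropy_bits: float
    avg_bigram_pmi_bits: Optional[float]
    jsd_vs_pool: float


@dataclass(frozen=True)
class CorpusProfile:
    """Corpus-level profile: pooled (concatenated-counts) entropies, the
    corpus-level average bigram PMI, and per-document profiles.

    Pooled entropies are computed on the sum of per-document count tables,
    not as means of per-document entropies; mean per-document entropies are
    reported separately.
    """

    label: str
    pooled_char_entropy_bits: float
    pooled_word_entropy_bits: float
    corpus_avg_bigram_pmi_bits: Optional[float]
    mean_doc_length_chars: float
    per_doc_profiles: tuple[DocProfile, ...]
    pmi_excluded_docs: int  # docs with no qualifying bigram at the per-doc floor


def _doc_words(doc: Document, use_normalized: bool = True) -> list[str]:
    return tokenize_words(doc.normalized_text if use_normalized else doc.raw_text)


def document_profile(
    doc: Document,
    pool: TokenDistribution,
    pmi_min_freq: int = 1,
    *,
    jsd_sqrt: bool = False,
    lowercase_chars: bool = False,
) -> DocProfile:
    """Compute the eight per-document features from the normalized text.

    ``pool`` is the word distribution the per-document JSD is measured
    against (combined corpora when comparing, own corpus when profiling).
    """
    text = doc.normalized_text
    words = tokenize_words(text)
    if not words:
        raise ValueError(f"document {doc.id!r} has no word tokens")
    chars = char_sequence(text.lower() if lowercase_chars else text)
    word_dist = distribution(words)
    return DocProfile(
        size_mb=doc.size_mb,
        word_count=len(words),
        unique_word_count=word_dist.support_size,
        char_length=len(chars),
        char_entropy_bits=shannon_entropy(distribution(chars)),
        word_entropy_bits=shannon_entropy(word_dist),
        avg_bigram_pmi_bits=average_bigram_pmi(word_dist, bigrams(words), pmi_min_freq),
        jsd_vs_pool=jensen_shannon_divergence(word_dist, pool, sqrt=jsd_sqrt),
    )


def corpus_word_distribution(corpus: Corpus) -> TokenDistribution:
    return pooled_distribution(_doc_words(d) for d in corpus)


def corpus_profile(
    corpus: Corpus,
    pmi_min_freq: int = 3,
    *,
    doc_pmi_min_freq: int = 1,
    pool: TokenDistribution | None = None,
    jsd_sqrt: bool = False,
    lowercase_chars: bool = False,
) -> CorpusProfile:
    """Profile a corpus.

    Per-document JSD is measured against ``pool`` when given, else against
    the corpus's own pooled word distribution.  ``pmi_min_freq`` is the
    corpus-level frequency floor (default 3); per-document PMI uses
    ``doc_pmi_min_freq`` (default 1).
    """
    word_streams = [_doc_words(d) for d in corpus]
    for doc, ws in zip(corpus, word_streams):
        if not ws:
            raise ValueError(f"document {doc.id!r} has no word tokens")
    pooled_words = pooled_distribution(word_streams)
    if pool is None:
        pool = pooled_words
    char_streams = [
        char_sequence(d.normalized_text.lower() if lowercase_chars else d.normalized_text)
        for d in corpus
    ]
    pooled_chars = pooled_distribution(char_streams)
    profiles = tuple(
        document_profile(
            d, pool, doc_pmi_min_freq, jsd_sqrt=jsd_sqrt, lowercase_chars=lowercase_chars
        )
        for d in corpus
    )
    return CorpusProfile(
        label=corpus.label,
        pooled_char_entropy_bits=shannon_entropy(pooled_chars),
        pooled_word_entropy_bits=shannon_entropy(pooled_words),
        corpus_avg_bigram_pmi_bits=average_bigram_pmi(
            pooled_words, pooled_bigrams(word_streams), pmi_min_freq
        ),
        mean_doc_length_chars=sum(len(cs) for cs in char_streams) / len(char_streams),
        per_doc_profiles=profiles,
        pmi_excluded_docs=sum(1 for p in profiles if p.avg_bigram_pmi_bits is None),
    )
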