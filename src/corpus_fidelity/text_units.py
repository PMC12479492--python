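"""Tokenization, n-grams and empirical token distributions.

The shared substrate for every metric in the package.  Words are lowercased
maximal runs of letters (including diacritics) and digits, with internal
hyphens and apostrophes retained — a robust convention for Dutch clinical
text with hyphenated compounds.  Character sequences preserve case,
whitespace and punctuation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence


class EmptyDistributionError(ValueError):
    """Raised when a distribution is requested for an empty token stream."""


_WORD_RE = re.compile(r"[^\W_]+(?:[-'’][^\W_]+)*", re.UNICODE)


def tokenize_words(text: str) -> list[str]:
    """Lowercased word tokens; punctuation and whitespace are discarded."""
    return [m.group(0) for m in _WORD_RE.finditer(text.lower())]


def char_sequence(text: str) -> list[str]:
    """The Unicode characters of ``text`` in order, case preserved."""
    return list(text)


@dataclass(frozen=True)
class TokenDistribution:
    """Empirical probability distribution over tokens, with raw counts.

    Probabilities are counts/total over the observed support only: absent
    tokens are absent, never zero-probability entries.
    """

    counts: Mapping[str, int]
    total: int

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "TokenDistribution":
        counts = {t: int(c) for t, c in counts.items() if c > 0}
        total = sum(counts.values())
        if total == 0:
            raise EmptyDistributionError("empty distribution: no tokens")
        return cls(counts=counts, total=total)

    @property
    def probs(self) -> dict[str, float]:
        return {t: c / self.total for t, c in self.counts.items()}

    def p(self, token: str) -> float:
        return self.counts.get(token, 0) / self.total

    @property
    def support_size(self) -> int:
        return len(self.counts)

    def merge(self, other: "TokenDistribution") -> "TokenDistribution":
        """Pool by summing counts (concatenated-counts convention)."""
        merged = dict(self.counts)
        for t, c in other.counts.items():
            merged[t] = merged.get(t, 0) + c
        return TokenDistribution.from_counts(merged)


def distribution(tokens: Sequence[str]) -> TokenDistribution:
    """Empirical distribution of a non-empty token stream."""
    if not tokens:
        raise EmptyDistributionError("empty distribution: no tokens")
    counts: dict[str, int] = {}
    for t in tokens:
        counts[t] = counts.get(t, 0) + 1
    return TokenDistribution(counts=counts, total=len(tokens))


@dataclass(frozen=True)
class BigramTable:
    """Counts of adjacent ordered token pairs within single streams.

    Streams are never concatenated across documents: a corpus-level table is
    the sum of per-document tables, so no bigram spans a document boundary.
    """

    counts: Mapping[tuple[str, str], int]
    total_bigrams: int

    @classmethod
    def empty(cls) -> "BigramTable":
        return cls(counts={}, total_bigrams=0)

    def merge(self, other: "BigramTable") -> "BigramTable":
        merged = dict(self.counts)
        for pair, c in other.counts.items():
            merged[pair] = merged.get(pair, 0) + c
        return BigramTable(counts=merged, total_bigrams=self.total_bigrams + other.total_bigrams)


def bigrams(tokens: Sequence[str]) -> BigramTable:
    """Adjacent ordered pairs of one token stream (empty for length < 2)."""
    counts: dict[tuple[str, str], int] = {}
    for a, b in zip(tokens, tokens[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return BigramTable(counts=counts, total_bigrams=max(len(tokens) - 1, 0))


def pooled_distribution(token_streams: Iterable[Sequence[str]]) -> TokenDistribution:
    """Distribution of summed per-stream count tables."""
    counts: dict[str, int] = {}
    n = 0
    for stream in token_streams:
        for t in stream:
            counts[t] = counts.get(t, 0) + 1
            n += 1
    if n == 0:
        raise EmptyDistributionError("empty distribution: no tokens in any stream")
    return TokenDistribution(counts=counts, total=n)


def pooled_bigrams(token_streams: Iterable[Sequence[str]]) -> BigramTable:
    """Sum of per-stream bigram tables; pairs never cross stream boundaries."""
    table = BigramTable.empty()
    for stream in token_streams:
        table = table.merge(bigrams(stream))
    return table
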