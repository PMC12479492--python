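"""Corpus BLEU implemented from its definition.

Measures surface-level lexical overlap between a synthetic corpus (the
candidates) and a reference corpus.  Every reference document serves as part
of the multi-reference set for every candidate — the study never pairs
specific synthetic notes with specific source notes — so modified n-gram
precisions are clipped against the best single reference and the brevity
penalty uses the closest-reference-length convention.  Zero precisions are
floored at a small epsilon before the geometric mean (documented smoothing),
so disjoint corpora score near, but not exactly, zero.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .corpus_io import Corpus
from .text_units import tokenize_words

EPSILON = 1e-9


@dataclass(frozen=True)
class BleuResult:
    """Corpus BLEU on the 0-100 scale with its components."""

    score: float
    modified_precisions: tuple[float, ...]
    brevity_penalty: float
    candidate_length: int
    effective_reference_length: int


def _ngram_counts(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def modified_ngram_precision(
    candidates: Sequence[Sequence[str]],
    references: Sequence[Sequence[str]],
    n: int,
) -> tuple[int, int]:
    """Clipped n-gram matches and total candidate n-grams, corpus-summed.

    Each candidate n-gram count is clipped at the maximum count of that
    n-gram in any single reference.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    max_ref: dict[tuple, int] = {}
    for ref in references:
        for gram, c in _ngram_counts(ref, n).items():
            if c > max_ref.get(gram, 0):
                max_ref[gram] = c
    clipped = 0
    total = 0
    for cand in candidates:
        counts = _ngram_counts(cand, n)
        total += sum(counts.values())
        clipped += sum(min(c, max_ref.get(gram, 0)) for gram, c in counts.items())
    return clipped, total


def _closest_ref_length(cand_len: int, ref_lengths: Sequence[int]) -> int:
    # ties broken toward the shorter reference, the standard convention
    return min(ref_lengths, key=lambda r: (abs(r - cand_len), r))


def bleu_from_token_lists(
    candidates: Sequence[Sequence[str]],
    references: Sequence[Sequence[str]],
    max_n: int = 4,
    epsilon: float = EPSILON,
) -> BleuResult:
    if not candidates or not references:
        raise ValueError("candidates and references must be non-empty")
    ref_lengths = [len(r) for r in references]
    cand_length = sum(len(c) for c in candidates)
    eff_ref_length = sum(_closest_ref_length(len(c), ref_lengths) for c in candidates)

    precisions = []
    for n in range(1, max_n + 1):
        clipped, total = modified_ngram_precision(candidates, references, n)
        precisions.append(clipped / total if total > 0 else 0.0)

    log_sum = sum(math.log(max(p, epsilon)) for p in precisions) / max_n
    if cand_length == 0:
        bp = 0.0
    elif cand_length > eff_ref_length:
        bp = 1.0
    else:
        bp = math.exp(1.0 - eff_ref_length / cand_length)
    score = 100.0 * bp * math.exp(log_sum)
    return BleuResult(
        score=score,
        modified_precisions=tuple(precisions),
        brevity_penalty=bp,
        candidate_length=cand_length,
        effective_reference_length=eff_ref_length,
    )


def corpus_bleu(
    synthetic: Corpus,
    reference: Corpus,
    max_n: int = 4,
    *,
    pairing: str = "multi_reference",
) -> BleuResult:
    """Corpus BLEU of the synthetic corpus against the reference corpus.

    ``pairing='multi_reference'`` (default): every reference document is a
    reference for every synthetic candidate.  ``pairing='best_match'``: each
    candidate is scored against its single best-BLEU reference; the corpus
    statistics are then aggregated over those pairs.  The pairing changes the
    number — the default is the common corpus-BLEU convention.
    """
    cands = [tokenize_words(d.normalized_text) for d in synthetic]
    refs = [tokenize_words(d.normalized_text) for d in reference]
    if pairing == "multi_reference":
        return bleu_from_token_lists(cands, refs, max_n=max_n)
    if pairing == "best_match":
        chosen = []
        for cand in cands:
            best = max(refs, key=lambda r: bleu_from_token_lists([cand], [r], max_n).score)
            chosen.append(best)
        # aggregate corpus-style over the chosen pairs
        clipped_tot = [0] * max_n
        total_tot = [0] * max_n
        cand_length = 0
        eff_ref_length = 0
        for cand, ref in zip(cands, chosen):
            cand_length += len(cand)
            eff_ref_length += len(ref)
            for n in range(1, max_n + 1):
                c, t = modified_ngram_precision([cand], [ref], n)
                clipped_tot[n - 1] += c
                total_tot[n - 1] += t
        precisions = [c / t if t else 0.0 for c, t in zip(clipped_tot, total_tot)]
        log_sum = sum(math.log(max(p, EPSILON)) for p in precisions) / max_n
        bp = 1.0 if cand_length > eff_ref_length else (
            math.exp(1.0 - eff_ref_length / cand_length) if cand_length else 0.0
        )
        return BleuResult(
            score=100.0 * bp * math.exp(log_sum),
            modified_precisions=tuple(precisions),
            brevity_penalty=bp,
            candidate_length=cand_length,
            effective_reference_length=eff_ref_length,
        )
    raise ValueError(f"unknown pairing {pairing!r}")
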