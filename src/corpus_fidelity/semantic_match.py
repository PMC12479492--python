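"""Greedy embedding-based semantic matching (BERTScore-style).

Precision is the mean over candidate tokens of the best cosine similarity to
any reference token; recall the mirror image over reference tokens; F1 their
harmonic mean.  The embedder is a pluggable contract: any object exposing
``name``, ``dim`` and ``embed(tokens) -> (len(tokens), dim) unit-row array``
works, so a contextual transformer can be slotted in where one is available.
The package ships a deterministic seeded hash embedder so the whole pipeline
runs offline and bit-reproducibly; scores from different embedders are
labeled and must never be compared across embedders.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .corpus_io import Corpus
from .text_units import tokenize_words


class Embedder(Protocol):
    name: str
    dim: int

    def embed(self, tokens: Sequence[str]) -> np.ndarray:  # (n_tokens, dim), unit rows
        ...


@dataclass(frozen=True)
class SemanticScore:
    precision: float
    recall: float
    f1: float
    pair_count: int
    embedder: str = ""


class HashEmbedder:
    """Deterministic static token embedder.

    Each distinct token is mapped, via a seeded BLAKE2 hash of the token
    string, to a fixed unit vector drawn from an isotropic Gaussian, so
    identical tokens always share a vector and distinct tokens are
    near-orthogonal in expectation at moderate dimension.  Context-free by
    construction: a stand-in contract implementation, not a language model.
    """

    def __init__(self, seed: int = 0, dim: int = 256):
        if dim < 8:
            raise ValueError("dim must be >= 8")
        self.seed = int(seed)
        self.dim = int(dim)
        self.name = f"hash-{self.seed}-d{self.dim}"
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, token: str) -> np.ndarray:
        v = self._cache.get(token)
        if v is None:
            digest = hashlib.blake2b(
                token.encode("utf-8"), digest_size=8, key=str(self.seed).encode()
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            v = rng.standard_normal(self.dim)
            v /= np.linalg.norm(v)
            self._cache[token] = v
        return v

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        if len(tokens) == 0:
            return np.empty((0, self.dim))
        return np.stack([self._vector(t) for t in tokens])


def hash_embedder(seed: int = 0, dim: int = 256) -> HashEmbedder:
    return HashEmbedder(seed=seed, dim=dim)


def greedy_match_score(
    candidate_tokens: Sequence[str],
    reference_tokens: Sequence[str],
    embedder: Embedder,
) -> SemanticScore:
    """Greedy max-cosine matching between two token lists.

    recall = mean over reference tokens of max cosine to candidate tokens;
    precision = mean over candidate tokens of max cosine to reference tokens.
    No IDF weighting.
    """
    if not candidate_tokens or not reference_tokens:
        raise ValueError("token lists must be non-empty")
    C = embedder.embed(candidate_tokens)  # (nc, d)
    R = embedder.embed(reference_tokens)  # (nr, d)
    S = R @ C.T  # S[i, j] = cos(ref_i, cand_j); rows are unit vectors
    recall = float(S.max(axis=1).mean())
    precision = float(S.max(axis=0).mean())
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return SemanticScore(
        precision=precision, recall=recall, f1=f1, pair_count=1, embedder=embedder.name
    )


def corpus_semantic_score(
    synthetic: Corpus,
    reference: Corpus,
    embedder: Embedder,
    aggregation: str = "all_pairs",
) -> SemanticScore:
    """Aggregate document-pair scores over two corpora.

    ``all_pairs``: mean precision/recall/F1 over every (synthetic, reference)
    document pair.  ``best_match``: for each synthetic document keep the
    reference pair with maximal F1, then average.
    """
    cand_tokens = [tokenize_words(d.normalized_text) for d in synthetic]
    ref_tokens = [tokenize_words(d.normalized_text) for d in reference]
    if aggregation == "all_pairs":
        scores = [
            greedy_match_score(c, r, embedder) for c in cand_tokens for r in ref_tokens
        ]
    elif aggregation == "best_match":
        scores = [
            max(
                (greedy_match_score(c, r, embedder) for r in ref_tokens),
                key=lambda s: s.f1,
            )
            for c in cand_tokens
        ]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    P = float(np.mean([s.precision for s in scores]))
    R = float(np.mean([s.recall for s in scores]))
    f1 = float(np.mean([s.f1 for s in scores]))
    return SemanticScore(
        precision=P, recall=R, f1=f1, pair_count=len(scores), embedder=embedder.name
    )
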