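"""Pluggable backends for the automated metrics.

Three contracts are defined here:

* :class:`EmbeddingProvider` — tokenize text and embed each token as a
  fixed-dimension vector (the BERTScore-family plug point; real clinical
  encoders such as SapBERT/clinicalBERT/PubMedBERT are external
  configurations of this contract).
* :class:`ConceptExtractor` — map text to a set of concept identifiers
  (CUI-like strings).  Real UMLS access is an external adapter; the
  bundled extractor is a longest-match dictionary lookup.
* :class:`ConditionalScorer` — sum of token log-probabilities of a
  candidate given a reference (the BARTScore-style plug point).

The bundled implementations are deliberately small and deterministic so
the metric layer is fully testable offline.
"""

from __future__ import annotations

import hashlib
import math
import re
from abc import ABC, abstractmethod
from collections import Counter
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "tokenize",
    "EmbeddingProvider",
    "OneHotEmbeddingProvider",
    "HashedEmbeddingProvider",
    "ConceptExtractor",
    "DictionaryConceptExtractor",
    "ConditionalScorer",
    "BigramConditionalScorer",
    "UniformConditionalScorer",
    "ExternalRegressionAdapter",
]

_PUNCT_RE = re.compile(r"[^\w\s]")


def tokenize(text: str, case_fold: bool = True) -> list[str]:
    """Default tokenizer: lowercase, strip punctuation, whitespace split."""
    if case_fold:
        text = text.lower()
    return _PUNCT_RE.sub(" ", text).split()


class EmbeddingProvider(ABC):
    """Contract: deterministic per-token embeddings of constant dimension."""

    backend_id: str = "embedding"

    def tokenize(self, text: str) -> list[str]:
        return tokenize(text)

    @abstractmethod
    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        """Return an array of shape (len(tokens), dim)."""


class OneHotEmbeddingProvider(EmbeddingProvider):
    """One-hot token embeddings over a vocabulary.

    With these embeddings the greedy-match F-score reduces exactly to
    type-level token-overlap precision/recall, which makes this provider
    the canonical test backend.  The vocabulary may be fixed up front or
    grown lazily inside a fixed ``capacity`` (the embedding dimension,
    constant per provider as the contract requires); lazy growth is
    deterministic for a fixed call sequence, and metric values depend
    only on token identity, not index assignment.
    """

    backend_id = "onehot"

    def __init__(
        self,
        vocabulary: Sequence[str] | None = None,
        capacity: int = 4096,
    ):
        self._index: dict[str, int] = {}
        self._frozen = vocabulary is not None
        if vocabulary is not None:
            for tok in vocabulary:
                self._index.setdefault(tok, len(self._index))
            capacity = max(capacity, len(self._index))
        self.capacity = capacity

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        for tok in tokens:
            if tok not in self._index:
                if self._frozen:
                    raise KeyError(f"token {tok!r} outside fixed vocabulary")
                if len(self._index) >= self.capacity:
                    raise ValueError(
                        f"one-hot vocabulary exceeded capacity {self.capacity}"
                    )
                self._index[tok] = len(self._index)
        out = np.zeros((len(tokens), self.capacity))
        for i, tok in enumerate(tokens):
            out[i, self._index[tok]] = 1.0
        return out


class HashedEmbeddingProvider(EmbeddingProvider):
    """Deterministic pseudo-random unit vectors keyed by token hash.

    A stand-in semantic space for tests and simulations: distinct tokens
    get near-orthogonal directions in ``dim`` dimensions, identical tokens
    always the same vector.  Synthetic — carries no linguistic knowledge.
    """

    backend_id = "hashed"

    def __init__(self, dim: int = 64):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim

    def _vector(self, token: str) -> np.ndarray:
        digest = hashlib.sha256(token.encode("utf-8")).digest()
        seed = int.from_bytes(digest[:4], "big")
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(self.dim)
        return v / np.linalg.norm(v)

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            return np.zeros((0, self.dim))
        return np.stack([self._vector(t) for t in tokens])


class ConceptExtractor(ABC):
    """Contract: deterministic text -> set of concept identifiers."""

    backend_id: str = "concepts"

    @abstractmethod
    def extract(self, text: str) -> set[str]:
        ...


class DictionaryConceptExtractor(ConceptExtractor):
    """Greedy longest-match lookup against a surface-string lexicon.

    ``lexicon`` maps surface strings (possibly multi-word) to CUI-like
    identifiers.  Matching is case-insensitive on the default-tokenized
    text and prefers the longest span starting at each position.
    """

    backend_id = "dict-lookup"

    def __init__(self, lexicon: Mapping[str, str]):
        self._entries: dict[tuple[str, ...], str] = {}
        for surface, cui in lexicon.items():
            key = tuple(tokenize(surface))
            if key:
                self._entries[key] = cui
        self._max_len = max((len(k) for k in self._entries), default=1)

    def extract(self, text: str) -> set[str]:
        toks = tokenize(text)
        found: set[str] = set()
        i = 0
        while i < len(toks):
            matched = 0
            for span in range(min(self._max_len, len(toks) - i), 0, -1):
                cui = self._entries.get(tuple(toks[i : i + span]))
                if cui is not None:
                    found.add(cui)
                    matched = span
                    break
            i += matched or 1
        return found


class ConditionalScorer(ABC):
    """Contract: log P(candidate | reference), summed over tokens."""

    backend_id: str = "conditional"

    @abstractmethod
    def logprob(self, candidate: str, reference: str) -> float:
        ...


class BigramConditionalScorer(ConditionalScorer):
    """Laplace-smoothed bigram model fit on the reference at call time.

    Scores sum of per-token log-probabilities of the candidate under a
    bigram distribution estimated from the reference with add-``alpha``
    smoothing over a vocabulary of reference tokens plus one unknown
    symbol.  Higher is better; 0 only for an empty candidate.
    """

    backend_id = "toy-bigram"
    _BOS = "<s>"
    _UNK = "<unk>"

    def __init__(self, alpha: float = 1.0):
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.alpha = alpha

    def logprob(self, candidate: str, reference: str) -> float:
        cand = tokenize(candidate)
        ref = tokenize(reference)
        vocab = set(ref) | {self._UNK}
        V = len(vocab)
        bigrams = Counter(zip([self._BOS] + ref[:-1], ref))
        unigrams = Counter([self._BOS] + ref[:-1])
        total = 0.0
        prev = self._BOS
        for tok in cand:
            tok_v = tok if tok in vocab else self._UNK
            num = bigrams.get((prev, tok_v), 0) + self.alpha
            den = unigrams.get(prev, 0) + self.alpha * V
            total += math.log(num / den)
            prev = tok_v
        return total


class UniformConditionalScorer(ConditionalScorer):
    """Uniform distribution over a fixed vocabulary size; closed form
    ``n * log(1/V)`` for a candidate of n tokens."""

    backend_id = "uniform"

    def __init__(self, vocab_size: int):
        if vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        self.vocab_size = vocab_size

    def logprob(self, candidate: str, reference: str) -> float:
        n = len(tokenize(candidate))
        return n * math.log(1.0 / self.vocab_size)


class ExternalRegressionAdapter:
    """Adapter for learned-regression metrics (COMET/BLEURT-style).

    Wraps any callable ``(candidate, reference) -> float`` — typically a
    subprocess or service call to an externally hosted model.  Such
    metrics are never reimplemented here and are excluded from the
    default suite.
    """

    def __init__(
        self, score_fn: Callable[[str, str], float], backend_id: str
    ):
        self._fn = score_fn
        self.backend_id = backend_id

    def score(self, candidate: str, reference: str) -> float:
        return float(self._fn(candidate, reference))
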