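"""Automated evaluation metrics over candidate/reference diagnosis text.

Implemented from first principles over the pluggable backends in
:mod:`dxeval.backends`:

* ROUGE-L — longest-common-subsequence precision/recall/F (beta = 1).
* Greedy-match F-score — the BERTScore-family statistic: for each token
  the maximum pairwise cosine similarity to the other side, averaged into
  precision (over candidate tokens) and recall (over reference tokens).
* Concept F-score — set precision/recall/F over extracted concept
  identifiers (the CUI F-score when the extractor is UMLS-backed).
* Graph-embedding F-score — greedy matching applied to concept
  embeddings instead of token embeddings (one reading of a knowledge-
  graph-embedding scorer; the aggregation is not standardised).
* Log-probability score — sum of candidate token log-probabilities given
  the reference under a conditional sequence model (BARTScore-style;
  higher is better, unbounded below).

Conventions: any precision or recall whose denominator is empty is
reported as 0 with a logged warning, and cosine similarity involving a
zero vector is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .backends import (
    ConceptExtractor,
    ConditionalScorer,
    EmbeddingProvider,
    ExternalRegressionAdapter,
    tokenize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TextPair",
    "MetricScore",
    "lcs_length",
    "rouge_l",
    "greedy_match_fscore",
    "concept_fscore",
    "graph_embedding_fscore",
    "logprob_score",
    "MetricSuite",
    "run_metric_suite",
]


@dataclass(frozen=True)
class TextPair:
    """One candidate/reference text pair (empty strings permitted)."""

    pair_id: str
    candidate: str
    reference: str


@dataclass(frozen=True)
class MetricScore:
    """One metric's value for one pair, with backend provenance."""

    pair_id: str
    metric_name: str
    value: float
    precision: float | None = None
    recall: float | None = None
    backend_id: str = ""


def lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Length of the longest common subsequence of two token lists.

    Standard O(|a|·|b|) dynamic programme; symmetric, bounded by
    min(|a|, |b|).
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        curr = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                curr[j] = prev[j - 1] + 1
            else:
                curr[j] = max(prev[j], curr[j - 1])
        prev = curr
    return prev[m]


def _f_beta1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def rouge_l(pair: TextPair, case_fold: bool = True) -> MetricScore:
    """ROUGE-L: LCS-based precision, recall and F1 over tokens.

    P = LCS/|candidate|, R = LCS/|reference|, F = harmonic mean.  Empty
    sides follow the zero-denominator convention.
    """
    cand = tokenize(pair.candidate, case_fold=case_fold)
    ref = tokenize(pair.reference, case_fold=case_fold)
    if not cand or not ref:
        if not cand and not ref:
            logger.warning("rouge_l: both texts empty for pair %s", pair.pair_id)
        else:
            logger.warning("rouge_l: empty side for pair %s", pair.pair_id)
        return MetricScore(pair.pair_id, "rouge_l", 0.0, 0.0, 0.0, "token-lcs")
    lcs = lcs_length(cand, ref)
    p = lcs / len(cand)
    r = lcs / len(ref)
    return MetricScore(
        pair.pair_id, "rouge_l", _f_beta1(p, r), p, r, "token-lcs"
    )


def _greedy_match(
    cand_emb: np.ndarray, ref_emb: np.ndarray
) -> tuple[float, float]:
    """(precision, recall) of greedy max-cosine matching.

    Zero vectors have similarity 0 to everything.
    """
    cn = np.linalg.norm(cand_emb, axis=1, keepdims=True)
    rn = np.linalg.norm(ref_emb, axis=1, keepdims=True)
    cu = np.divide(cand_emb, cn, out=np.zeros_like(cand_emb), where=cn > 0)
    ru = np.divide(ref_emb, rn, out=np.zeros_like(ref_emb), where=rn > 0)
    sim = cu @ ru.T  # (n_cand, n_ref)
    precision = float(sim.max(axis=1).mean())
    recall = float(sim.max(axis=0).mean())
    return precision, recall


def greedy_match_fscore(
    pair: TextPair,
    provider: EmbeddingProvider,
    metric_name: str = "greedy_match",
    clip_negative: bool = True,
) -> MetricScore:
    """BERTScore-family greedy-matching F over token embeddings.

    Recall averages, over reference tokens, the maximum cosine similarity
    to any candidate token; precision symmetrically over candidate
    tokens.  With unit-norm embeddings each lies in [-1, 1]; negative
    values are clipped to 0 before the harmonic mean by default so F
    stays in [0, 1].
    """
    cand = provider.tokenize(pair.candidate)
    ref = provider.tokenize(pair.reference)
    if not cand or not ref:
        logger.warning(
            "greedy_match_fscore: empty token sequence for pair %s",
            pair.pair_id,
        )
        return MetricScore(
            pair.pair_id, metric_name, 0.0, 0.0, 0.0, provider.backend_id
        )
    cand_emb = provider.embed(cand)
    ref_emb = provider.embed(ref)
    if cand_emb.shape[1] != ref_emb.shape[1]:
        raise ValueError(
            f"embedding dimension mismatch for pair {pair.pair_id}: "
            f"{cand_emb.shape[1]} vs {ref_emb.shape[1]}"
        )
    p, r = _greedy_match(cand_emb, ref_emb)
    if clip_negative:
        p, r = max(p, 0.0), max(r, 0.0)
    return MetricScore(
        pair.pair_id, metric_name, _f_beta1(p, r), p, r, provider.backend_id
    )


def concept_fscore(
    pair: TextPair, extractor: ConceptExtractor
) -> MetricScore:
    """Set precision/recall/F over extracted concept identifiers."""
    cand = extractor.extract(pair.candidate)
    ref = extractor.extract(pair.reference)
    if not cand or not ref:
        if not cand and not ref:
            logger.warning(
                "concept_fscore: no concepts on either side for pair %s",
                pair.pair_id,
            )
        return MetricScore(
            pair.pair_id, "concept_fscore", 0.0, 0.0, 0.0,
            extractor.backend_id,
        )
    overlap = len(cand & ref)
    p = overlap / len(cand)
    r = overlap / len(ref)
    return MetricScore(
        pair.pair_id, "concept_fscore", _f_beta1(p, r), p, r,
        extractor.backend_id,
    )


def graph_embedding_fscore(
    pair: TextPair,
    extractor: ConceptExtractor,
    concept_embedder: Mapping[str, np.ndarray] | Callable[[str], np.ndarray],
    metric_name: str = "graph_embedding_fscore",
) -> MetricScore:
    """Greedy-matching F over *concept* embeddings.

    Concepts are extracted from each side and embedded (e.g. by a
    knowledge-graph embedding table); matching then proceeds exactly as
    in :func:`greedy_match_fscore`.  Concepts are ordered by identifier
    for determinism; greedy matching is order-invariant anyway.
    """
    embed = (
        concept_embedder.__getitem__
        if isinstance(concept_embedder, Mapping)
        else concept_embedder
    )
    cand = sorted(extractor.extract(pair.candidate))
    ref = sorted(extractor.extract(pair.reference))
    backend = f"{extractor.backend_id}+graph-embedding"
    if not cand or not ref:
        logger.warning(
            "graph_embedding_fscore: empty concept set for pair %s",
            pair.pair_id,
        )
        return MetricScore(pair.pair_id, metric_name, 0.0, 0.0, 0.0, backend)
    cand_emb = np.stack([np.asarray(embed(c), dtype=float) for c in cand])
    ref_emb = np.stack([np.asarray(embed(c), dtype=float) for c in ref])
    if cand_emb.shape[1] != ref_emb.shape[1]:
        raise ValueError(
            f"concept embedding dimension mismatch for pair {pair.pair_id}"
        )
    p, r = _greedy_match(cand_emb, ref_emb)
    p, r = max(p, 0.0), max(r, 0.0)
    return MetricScore(
        pair.pair_id, metric_name, _f_beta1(p, r), p, r, backend
    )


def logprob_score(
    pair: TextPair, scorer: ConditionalScorer
) -> MetricScore:
    """Sum of candidate token log-probabilities given the reference.

    Higher is better; the value is unbounded below and is *not* an
    F-type score (no precision/recall components).
    """
    try:
        value = scorer.logprob(pair.candidate, pair.reference)
    except Exception as exc:
        raise RuntimeError(
            f"conditional scorer {scorer.backend_id!r} failed on pair "
            f"{pair.pair_id}"
        ) from exc
    return MetricScore(
        pair.pair_id, "logprob_score", float(value),
        backend_id=scorer.backend_id,
    )


@dataclass
class MetricSuite:
    """Named collection of metric callables ``TextPair -> MetricScore``.

    ``register`` binds a backend into a closure; ``run`` applies every
    metric to every pair.  A metric whose backend raises
    ``MissingBackend`` at registration time is skipped with a warning,
    never silently zeroed.
    """

    metrics: dict[str, Callable[[TextPair], MetricScore]] = field(
        default_factory=dict
    )

    def register(
        self, name: str, fn: Callable[[TextPair], MetricScore]
    ) -> None:
        self.metrics[name] = fn

    def register_adapter(
        self, name: str, adapter: ExternalRegressionAdapter
    ) -> None:
        def _run(pair: TextPair, _a=adapter, _n=name) -> MetricScore:
            return MetricScore(
                pair.pair_id, _n, _a.score(pair.candidate, pair.reference),
                backend_id=_a.backend_id,
            )

        self.metrics[name] = _run

    def run(
        self, pairs: Sequence[TextPair], metrics: Sequence[str] | None = None
    ) -> pd.DataFrame:
        names = list(metrics) if metrics is not None else list(self.metrics)
        unknown = [n for n in names if n not in self.metrics]
        if unknown:
            raise KeyError(
                f"unknown metric(s) {unknown}; available: "
                f"{sorted(self.metrics)}"
            )
        rows = []
        for pair in pairs:
            for name in names:
                s = self.metrics[name](pair)
                rows.append(
                    {
                        "pair_id": s.pair_id,
                        "metric_name": name,
                        "precision": s.precision,
                        "recall": s.recall,
                        "value": s.value,
                        "backend_id": s.backend_id,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "pair_id", "metric_name", "precision", "recall", "value",
                "backend_id",
            ],
        )


def run_metric_suite(
    pairs: Sequence[TextPair],
    suite: MetricSuite,
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Apply the suite to every pair; one row per (pair, metric)."""
    return suite.run(pairs, metrics=metrics)
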