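"""Shared fixtures: random valid annotation records and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from dxeval.framework import (
    DiagnosisItem,
    FrameworkConfig,
    RecordAnnotation,
    ReasoningSentenceItem,
)


def make_random_record(
    rng: np.random.Generator,
    record_id: str = "r1",
    cfg: FrameworkConfig | None = None,
    allow_empty_reasoning: bool = True,
) -> RecordAnnotation:
    """A random record that respects the branching instrument.

    Samples every item uniformly over its scale, with gating applied
    after the fact, so field combinations are much broader than the
    quality-coupled synthetic generator produces.
    """
    cfg = cfg or FrameworkConfig()
    sc = cfg.scales
    n_diag = int(rng.integers(1, 7))
    diagnoses = []
    for i in range(n_diag):
        acc = int(rng.integers(sc["accuracy"].min, sc["accuracy"].max + 1))
        plaus = spec = None
        if acc >= cfg.accuracy_gate:
            plaus = int(
                rng.integers(sc["plausibility"].min,
                             sc["plausibility"].max + 1)
            )
            if plaus >= cfg.plausibility_gate:
                spec = int(
                    rng.integers(sc["specificity"].min,
                                 sc["specificity"].max + 1)
                )
        diagnoses.append(
            DiagnosisItem(f"diagnosis {i}", acc, plaus, spec)
        )
    omission = int(rng.integers(sc["omission"].min, sc["omission"].max + 1))
    uncertainty = None
    if omission < sc["omission"].max:
        uncertainty = int(
            rng.integers(sc["uncertainty"].min, sc["uncertainty"].max + 1)
        )
    lo = 0 if allow_empty_reasoning else 1
    n_sent = int(rng.integers(lo, 6))
    sentences = tuple(
        ReasoningSentenceItem(
            f"sentence {j}",
            comprehension=int(rng.integers(1, 6)),
            rationale=int(rng.integers(1, 6)),
            recall=int(rng.integers(1, 6)),
        )
        for j in range(n_sent)
    )
    return RecordAnnotation(
        record_id=record_id,
        diagnoses=tuple(diagnoses),
        omission=omission,
        uncertainty=uncertainty,
        reasoning_sentences=sentences,
        reasoning_omission=int(rng.integers(0, 2)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def framework_config() -> FrameworkConfig:
    return FrameworkConfig()
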