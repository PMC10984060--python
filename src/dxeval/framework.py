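"""Human evaluation framework for LLM-generated diagnosis lists.

The instrument scores each generated output (one per progress note) in two
branches:

* **Diagnostic accuracy** — per-diagnosis Likert items Accuracy,
  Plausibility and Specificity, plus output-level Omission and Uncertainty.
  Branching: Plausibility is scored only for diagnoses judged accurate,
  Specificity only for plausible ones, and Uncertainty only when an
  omission occurred.  Values skipped by branching are imputed to 0.
* **Diagnostic reasoning** — per-sentence Likert items Comprehension,
  Rationale and Recall, worded so that 1 means "no evidence of a problem";
  they are inverted (``6 - x``) before averaging so higher is better,
  plus an output-level binary reasoning-omission item.

The record-level composites are

    D_i = (p̄_i + s̄_i + ō_i) / 15        (diagnostic accuracy, in [0, 1])
    R_i = (c̄_i + ē_i + ā_i) / 15        (diagnostic reasoning, in [0, 1])

where p̄/s̄ are means of plausibility/specificity over *all* diagnoses
(imputed zeros included), ō is the mean of the omission and uncertainty
values, and c̄/ē/ā are post-inversion means of the three sentence items.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosisItem",
    "ReasoningSentenceItem",
    "RecordAnnotation",
    "ScoredRecord",
    "ScaleDef",
    "FrameworkConfig",
    "Violation",
    "validate_record",
    "impute_branching",
    "invert_reasoning",
    "score_record",
    "score_cohort",
    "CohortSummary",
]

REASONING_COMPONENTS = ("comprehension", "rationale", "recall")


@dataclass(frozen=True)
class ScaleDef:
    """Likert scale bounds for one instrument component."""

    min: int
    max: int

    def contains(self, value: int) -> bool:
        return self.min <= value <= self.max


@dataclass(frozen=True)
class FrameworkConfig:
    """Scales, gating thresholds and inversion set of the instrument.

    Defaults: Accuracy, Plausibility and the three reasoning items are
    1–5; Specificity, Omission and Uncertainty are 0–5 (0 is reachable by
    annotation or by imputation).  A diagnosis passes the accuracy gate at
    Likert >= ``accuracy_gate`` (agree/strongly agree) and likewise for
    plausibility.  Uncertainty is asked only when the omission item sits
    below its scale maximum, i.e. when some omission occurred.
    """

    scales: dict[str, ScaleDef] = field(
        default_factory=lambda: {
            "accuracy": ScaleDef(1, 5),
            "plausibility": ScaleDef(1, 5),
            "specificity": ScaleDef(0, 5),
            "omission": ScaleDef(0, 5),
            "uncertainty": ScaleDef(0, 5),
            "comprehension": ScaleDef(1, 5),
            "rationale": ScaleDef(1, 5),
            "recall": ScaleDef(1, 5),
        }
    )
    accuracy_gate: int = 4
    plausibility_gate: int = 4
    inverted_components: tuple[str, ...] = REASONING_COMPONENTS
    # denominator of D and R: three components, each on a 0-5 span
    composite_denominator: float = 15.0

    def omission_occurred(self, omission: int) -> bool:
        """True when the omission item indicates something was omitted."""
        return omission < self.scales["omission"].max


@dataclass(frozen=True)
class DiagnosisItem:
    """One generated diagnosis with its branched Likert judgments."""

    diagnosis_text: str
    accuracy: int
    plausibility: int | None = None
    specificity: int | None = None


@dataclass(frozen=True)
class ReasoningSentenceItem:
    """One reasoning sentence with its three (raw, uninverted) judgments."""

    sentence_text: str
    comprehension: int
    rationale: int
    recall: int


@dataclass(frozen=True)
class RecordAnnotation:
    """All human judgments for one progress-note output."""

    record_id: str
    diagnoses: tuple[DiagnosisItem, ...]
    omission: int
    uncertainty: int | None = None
    reasoning_sentences: tuple[ReasoningSentenceItem, ...] = ()
    reasoning_omission: int = 0  # binary: 1 = explanation missing
    empty_output: bool = False
    # True once invert_reasoning has run; guards double inversion in scoring
    reasoning_inverted: bool = False

    def __post_init__(self):
        object.__setattr__(self, "diagnoses", tuple(self.diagnoses))
        object.__setattr__(
            self, "reasoning_sentences", tuple(self.reasoning_sentences)
        )


@dataclass(frozen=True)
class ScoredRecord:
    """Component means and composite scores for one record.

    ``R`` is NaN for records without reasoning sentences; such records are
    excluded from reasoning summaries.
    """

    record_id: str
    p_bar: float
    s_bar: float
    o_bar: float
    c_bar: float
    e_bar: float
    a_bar: float
    D: float
    R: float


@dataclass(frozen=True)
class Violation:
    record_id: str
    component: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.record_id}] {self.component}: {self.rule}"


def _check_range(
    out: list[Violation], rec_id: str, component: str, value: int | None,
    cfg: FrameworkConfig,
) -> None:
    if value is None:
        return
    scale = cfg.scales[component]
    if not scale.contains(value):
        out.append(
            Violation(
                rec_id, component,
                f"value {value} outside scale [{scale.min}, {scale.max}]",
            )
        )


def validate_record(
    rec: RecordAnnotation, cfg: FrameworkConfig | None = None
) -> list[Violation]:
    """Check range and branching invariants; return violations, never raise.

    An empty list means the record is structurally sound and may be scored.
    """
    cfg = cfg or FrameworkConfig()
    out: list[Violation] = []

    if not rec.diagnoses and not rec.empty_output:
        out.append(
            Violation(
                rec.record_id, "diagnoses",
                "no diagnoses and empty_output flag not set",
            )
        )

    for idx, d in enumerate(rec.diagnoses):
        tag = f"diagnosis[{idx}]"
        _check_range(out, rec.record_id, "accuracy", d.accuracy, cfg)
        _check_range(out, rec.record_id, "plausibility", d.plausibility, cfg)
        _check_range(out, rec.record_id, "specificity", d.specificity, cfg)
        accurate = d.accuracy >= cfg.accuracy_gate
        if d.plausibility is not None and not accurate:
            out.append(
                Violation(
                    rec.record_id, f"{tag}.plausibility",
                    "plausibility scored although the diagnosis failed the "
                    "accuracy gate",
                )
            )
        plausible = (
            d.plausibility is not None
            and d.plausibility >= cfg.plausibility_gate
        )
        if d.specificity is not None and not plausible:
            out.append(
                Violation(
                    rec.record_id, f"{tag}.specificity",
                    "specificity scored although the diagnosis failed the "
                    "plausibility gate",
                )
            )

    _check_range(out, rec.record_id, "omission", rec.omission, cfg)
    _check_range(out, rec.record_id, "uncertainty", rec.uncertainty, cfg)
    if rec.uncertainty is not None and not cfg.omission_occurred(rec.omission):
        out.append(
            Violation(
                rec.record_id, "uncertainty",
                "uncertainty scored although omission indicates nothing "
                "was omitted",
            )
        )

    for idx, s in enumerate(rec.reasoning_sentences):
        for comp in REASONING_COMPONENTS:
            _check_range(out, rec.record_id, comp, getattr(s, comp), cfg)
    if rec.reasoning_omission not in (0, 1):
        out.append(
            Violation(
                rec.record_id, "reasoning_omission",
                f"binary item has value {rec.reasoning_omission}",
            )
        )
    return out


def impute_branching(
    rec: RecordAnnotation, cfg: FrameworkConfig | None = None
) -> RecordAnnotation:
    """Replace values absent *because of branching* with 0.

    A diagnosis that failed the accuracy gate gets plausibility 0 and
    specificity 0; one that failed the plausibility gate gets specificity
    0; uncertainty becomes 0 when no omission occurred.  An absent value
    the branching rules do not explain marks a corrupt export and raises
    ``ValueError``.  Idempotent.
    """
    cfg = cfg or FrameworkConfig()
    new_diagnoses = []
    for idx, d in enumerate(rec.diagnoses):
        plaus, spec = d.plausibility, d.specificity
        accurate = d.accuracy >= cfg.accuracy_gate
        if plaus is None:
            if accurate:
                raise ValueError(
                    f"record {rec.record_id} diagnosis[{idx}]: plausibility "
                    "absent although the diagnosis passed the accuracy gate"
                )
            plaus = 0
        plausible = plaus >= cfg.plausibility_gate
        if spec is None:
            if accurate and plausible:
                raise ValueError(
                    f"record {rec.record_id} diagnosis[{idx}]: specificity "
                    "absent although the diagnosis passed the plausibility "
                    "gate"
                )
            spec = 0
        new_diagnoses.append(replace(d, plausibility=plaus, specificity=spec))

    unc = rec.uncertainty
    if unc is None:
        if cfg.omission_occurred(rec.omission):
            raise ValueError(
                f"record {rec.record_id}: uncertainty absent although an "
                "omission occurred"
            )
        unc = 0
    return replace(rec, diagnoses=tuple(new_diagnoses), uncertainty=unc)


def invert_reasoning(rec: RecordAnnotation) -> RecordAnnotation:
    """Map each reasoning item x to 6 - x (an involution on {1..5}).

    The raw items are worded so 1 = no evidence of a problem; inversion
    makes higher uniformly better before averaging.
    """
    new_sentences = []
    for idx, s in enumerate(rec.reasoning_sentences):
        vals = {}
        for comp in REASONING_COMPONENTS:
            x = getattr(s, comp)
            if not 1 <= x <= 5:
                raise ValueError(
                    f"record {rec.record_id} sentence[{idx}].{comp}: value "
                    f"{x} outside {{1..5}}, cannot invert"
                )
            vals[comp] = 6 - x
        new_sentences.append(replace(s, **vals))
    return replace(
        rec,
        reasoning_sentences=tuple(new_sentences),
        reasoning_inverted=not rec.reasoning_inverted,
    )


def score_record(
    rec: RecordAnnotation, cfg: FrameworkConfig | None = None
) -> ScoredRecord:
    """Score one record: validate -> impute -> invert -> average.

    Raises ``ValueError`` on a structurally invalid record (with the
    violations listed) or on zero diagnoses without the empty-output flag.
    Records without reasoning sentences get ``R = NaN``.
    """
    cfg = cfg or FrameworkConfig()
    violations = validate_record(rec, cfg)
    if violations:
        msgs = "; ".join(str(v) for v in violations)
        raise ValueError(f"record {rec.record_id} failed validation: {msgs}")
    if not rec.diagnoses:
        raise ValueError(
            f"record {rec.record_id}: no diagnoses to score "
            "(empty outputs carry no diagnostic accuracy score)"
        )

    rec = impute_branching(rec, cfg)
    if not rec.reasoning_inverted:
        rec = invert_reasoning(rec)

    p_bar = float(np.mean([d.plausibility for d in rec.diagnoses]))
    s_bar = float(np.mean([d.specificity for d in rec.diagnoses]))
    o_bar = (rec.omission + rec.uncertainty) / 2.0

    if rec.reasoning_sentences:
        c_bar = float(
            np.mean([s.comprehension for s in rec.reasoning_sentences])
        )
        a_bar = float(np.mean([s.rationale for s in rec.reasoning_sentences]))
        e_bar = float(np.mean([s.recall for s in rec.reasoning_sentences]))
        R = (c_bar + e_bar + a_bar) / cfg.composite_denominator
    else:
        c_bar = a_bar = e_bar = R = float("nan")

    D = (p_bar + s_bar + o_bar) / cfg.composite_denominator
    return ScoredRecord(
        record_id=rec.record_id,
        p_bar=p_bar, s_bar=s_bar, o_bar=o_bar,
        c_bar=c_bar, e_bar=e_bar, a_bar=a_bar,
        D=D, R=R,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level medians/IQRs and the component frequency table."""

    n_records: int
    n_diagnoses: int
    n_sentences: int
    median_D: float
    iqr_D: tuple[float, float]
    median_R: float
    iqr_R: tuple[float, float]
    n_records_with_reasoning: int
    component_frequencies: pd.DataFrame


def _median_iqr(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    if values.size == 0:
        nan = float("nan")
        return nan, (nan, nan)
    return (
        float(np.median(values)),
        (float(np.quantile(values, 0.25)), float(np.quantile(values, 0.75))),
    )


def score_cohort(
    records: Sequence[RecordAnnotation],
    cfg: FrameworkConfig | None = None,
) -> tuple[list[ScoredRecord], CohortSummary]:
    """Score every record and summarise the cohort.

    The frequency table reports, per component, how many scored units sit
    at each Likert level and the derived headline fractions (accurate,
    plausible, specific-or-highly-specific, no-omission, reasoning items
    at the "no evidence of a problem" level, reasoning omissions).
    """
    cfg = cfg or FrameworkConfig()
    if not records:
        raise ValueError("score_cohort requires at least one record")

    scored: list[ScoredRecord] = []
    for rec in records:
        try:
            scored.append(score_record(rec, cfg))
        except ValueError as exc:
            raise ValueError(f"while scoring record {rec.record_id}: {exc}") from exc

    D = np.array([s.D for s in scored])
    R = np.array([s.R for s in scored])
    R_valid = R[~np.isnan(R)]
    median_D, iqr_D = _median_iqr(D)
    median_R, iqr_R = _median_iqr(R_valid)

    freq = _component_frequencies(records, cfg)
    n_diag = sum(len(r.diagnoses) for r in records)
    n_sent = sum(len(r.reasoning_sentences) for r in records)
    summary = CohortSummary(
        n_records=len(records),
        n_diagnoses=n_diag,
        n_sentences=n_sent,
        median_D=median_D, iqr_D=iqr_D,
        median_R=median_R, iqr_R=iqr_R,
        n_records_with_reasoning=int(np.sum(~np.isnan(R))),
        component_frequencies=freq,
    )
    return scored, summary


def _component_frequencies(
    records: Sequence[RecordAnnotation], cfg: FrameworkConfig
) -> pd.DataFrame:
    rows = []

    def add(component: str, values: Iterable[int | None], positive) -> None:
        vals = [v for v in values if v is not None]
        n = len(vals)
        counts = pd.Series(vals).value_counts().sort_index()
        n_pos = sum(1 for v in vals if positive(v))
        rows.append(
            {
                "component": component,
                "n_scored": n,
                "n_positive": n_pos,
                "fraction_positive": (n_pos / n) if n else float("nan"),
                "level_counts": {int(k): int(v) for k, v in counts.items()},
            }
        )

    diags = [d for r in records for d in r.diagnoses]
    sents = [s for r in records for s in r.reasoning_sentences]
    add("accuracy", (d.accuracy for d in diags),
        lambda v: v >= cfg.accuracy_gate)
    add("plausibility", (d.plausibility for d in diags),
        lambda v: v >= cfg.plausibility_gate)
    # "specific or highly specific" = top two levels of the 0-5 scale
    spec_hi = cfg.scales["specificity"].max - 1
    add("specificity", (d.specificity for d in diags), lambda v: v >= spec_hi)
    add("omission", (r.omission for r in records),
        lambda v: v == cfg.scales["omission"].max)
    add("uncertainty", (r.uncertainty for r in records), lambda v: v >= 1)
    # raw reasoning items: 1 or 2 = little-to-no evidence of a problem
    for comp in REASONING_COMPONENTS:
        add(comp, (getattr(s, comp) for s in sents), lambda v: v <= 2)
    add("reasoning_omission", (r.reasoning_omission for r in records),
        lambda v: v == 1)
    return pd.DataFrame(rows)
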