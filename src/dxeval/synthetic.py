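"""Synthetic annotation cohorts with known ground truth.

Real inputs to this analysis (credentialed progress notes, LLM
generations and clinician annotations) cannot ship with the package, so
every downstream module is exercised on synthetic cohorts that emulate
the study shape: 186 note-level records, 3–5 diagnoses per record
(~768 total), 3–6 reasoning sentences per record (~828 total), branched
Likert responses, and a tunable latent correlation between human quality
and text overlap.

The generative model, per record i:

* latent quality q_i ~ Beta(a, b) (defaults a = b = 2);
* an overlap propensity u_i coupled to q_i through a Gaussian copula
  with correlation ρ* (``latent_quality_corr``): u_i = Φ(ρ* z(q_i) +
  √(1−ρ*²) ε_i).  The candidate diagnosis list reproduces a fraction
  ≈ u_i of the reference concepts; the remainder are hallucinations
  drawn from the rest of the lexicon;
* Likert items drawn by discretizing a normal around an affine map of
  q_i onto each scale (sd = ``noise_sd``), respecting the branching
  instrument by construction — accuracy/plausibility/specificity means
  rise with q_i, omission severity and raw (pre-inversion) reasoning
  evidence fall with q_i.

ρ* is the generator's ground truth: recovered correlations between the
human composite D and overlap-driven metrics should rise monotonically
with it, and vanish at ρ* = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .backends import DictionaryConceptExtractor
from .framework import (
    DiagnosisItem,
    FrameworkConfig,
    RecordAnnotation,
    ReasoningSentenceItem,
)

__all__ = [
    "GeneratorConfig",
    "Lexicon",
    "SyntheticCohort",
    "generate_lexicon",
    "generate_record",
    "generate_cohort",
]

_ONSETS = ["car", "neph", "pulm", "hep", "enter", "derm", "neur", "vasc",
           "oste", "my", "gastr", "cereb", "ren", "pancre", "thyr"]
_CODAS = ["itis", "osis", "opathy", "emia", "algia", "oma", "itis acuta",
          "ic failure", "ic shock", "al infarction"]
_QUALIFIERS = ["acute", "chronic", "severe", "recurrent", "secondary"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shape and coupling parameters of the synthetic cohort."""

    n_records: int = 186
    diagnoses_min: int = 3
    diagnoses_max: int = 5
    sentences_min: int = 3
    sentences_max: int = 6
    latent_quality_corr: float = 0.5  # rho*: quality-overlap coupling
    noise_sd: float = 0.8
    # baseline competence: Likert means sit at quality_floor even at q=0,
    # emulating cohorts where most generated diagnoses pass the gates
    quality_floor: float = 0.55
    lexicon_size: int = 60
    quality_beta_a: float = 2.0
    quality_beta_b: float = 2.0
    reference_min: int = 3
    reference_max: int = 5
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.latent_quality_corr <= 1.0:
            raise ValueError("latent_quality_corr must lie in [-1, 1]")
        if self.lexicon_size < 10:
            raise ValueError("lexicon_size must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class Lexicon:
    """Toy diagnosis lexicon: concept id -> surface variants + tier."""

    entries: pd.DataFrame  # columns: cui, surface, tier (1 row per variant)

    @property
    def cuis(self) -> list[str]:
        return sorted(self.entries["cui"].unique())

    def surface_map(self) -> dict[str, str]:
        """surface string -> cui, as consumed by the bundled extractor."""
        return dict(zip(self.entries["surface"], self.entries["cui"]))

    def primary_surface(self, cui: str) -> str:
        sub = self.entries[self.entries["cui"] == cui]
        return sub["surface"].iloc[0]

    def variants(self, cui: str) -> list[str]:
        return list(self.entries[self.entries["cui"] == cui]["surface"])

    def extractor(self) -> DictionaryConceptExtractor:
        return DictionaryConceptExtractor(self.surface_map())


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus the latent truth table."""

    records: list[RecordAnnotation]
    generations: pd.DataFrame  # record_id, candidate_raw, reference_raw
    truth: pd.DataFrame  # record_id, q, overlap, rho_star
    lexicon: Lexicon


def generate_lexicon(cfg: GeneratorConfig) -> Lexicon:
    """Deterministic toy lexicon of pseudoclinical diagnosis strings.

    Each concept gets a unique CUI-like id, a specificity tier in {1,2,3}
    and 1–3 surface variants (base term, qualified term, abbreviated
    term); every variant extracts back to its id under the bundled
    dictionary extractor.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    seen_bases: set[str] = set()
    i = 0
    while len(seen_bases) < cfg.lexicon_size:
        onset = _ONSETS[int(rng.integers(len(_ONSETS)))]
        coda = _CODAS[int(rng.integers(len(_CODAS)))]
        base = f"{onset}{coda}"
        i += 1
        if base in seen_bases:
            continue
        seen_bases.add(base)
        cui = f"CX{len(seen_bases):06d}"
        tier = int(rng.integers(1, 4))
        n_variants = int(rng.integers(1, 4))
        surfaces = [base]
        if n_variants >= 2:
            qual = _QUALIFIERS[int(rng.integers(len(_QUALIFIERS)))]
            surfaces.append(f"{qual} {base}")
        if n_variants >= 3:
            # concept index suffix keeps abbreviations collision-free
            abbrev = base[: max(4, len(base) // 2)].strip()
            surfaces.append(f"{abbrev}{len(seen_bases)}x")
        for s in surfaces:
            rows.append({"cui": cui, "surface": s, "tier": tier})
    return Lexicon(pd.DataFrame(rows))


def _likert(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    """Discretize N(mean, sd) onto the integer scale [lo, hi]."""
    if sd == 0:
        x = mean
    else:
        x = rng.normal(mean, sd)
    return int(np.clip(round(x), lo, hi))


def _scale_map(
    q: float, lo: int, hi: int, increasing: bool, floor: float = 0.0
) -> float:
    """Affine map of q in [0,1] onto [lo, hi].

    ``floor`` shifts the whole response band up (good direction) so that
    even low-quality outputs are not uniformly terrible; ``increasing``
    False reverses the direction (items where low raw values are good).
    """
    t = floor + (1.0 - floor) * q
    if not increasing:
        t = 1.0 - t
    return lo + t * (hi - lo)


def generate_record(
    cfg: GeneratorConfig,
    lexicon: Lexicon,
    q: float,
    record_id: str,
    rng: np.random.Generator,
    overlap: float | None = None,
    fw: FrameworkConfig | None = None,
) -> tuple[dict, RecordAnnotation, float]:
    """One synthetic record at latent quality ``q``.

    Returns the generation row (record_id, candidate/reference raw
    text), the branched annotation, and the realized concept overlap
    fraction.  ``overlap`` defaults to ``q`` itself (the ρ* coupling is
    applied by :func:`generate_cohort`).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    fw = fw or FrameworkConfig()
    if overlap is None:
        overlap = q
    cuis = lexicon.cuis

    n_ref = int(rng.integers(cfg.reference_min, cfg.reference_max + 1))
    ref_cuis = list(rng.choice(cuis, size=n_ref, replace=False))
    n_cand = int(rng.integers(cfg.diagnoses_min, cfg.diagnoses_max + 1))
    n_keep = min(int(round(overlap * n_cand)), n_ref, n_cand)
    kept = list(rng.choice(ref_cuis, size=n_keep, replace=False))
    pool = [c for c in cuis if c not in ref_cuis]
    halluc = list(rng.choice(pool, size=n_cand - n_keep, replace=False))
    cand_cuis = kept + halluc
    rng.shuffle(cand_cuis)

    def surface(cui: str) -> str:
        variants = lexicon.variants(cui)
        return variants[int(rng.integers(len(variants)))]

    cand_texts = [surface(c) for c in cand_cuis]
    ref_texts = [lexicon.primary_surface(c) for c in ref_cuis]

    sc = fw.scales
    diagnoses = []
    for cui, cand_text in zip(cand_cuis, cand_texts):
        q_eff = q
        acc = _likert(
            rng, _scale_map(q_eff, sc["accuracy"].min, sc["accuracy"].max, True,
                       cfg.quality_floor),
            cfg.noise_sd, sc["accuracy"].min, sc["accuracy"].max,
        )
        plaus = spec = None
        if acc >= fw.accuracy_gate:
            plaus = _likert(
                rng,
                _scale_map(q_eff, sc["plausibility"].min,
                           sc["plausibility"].max, True, cfg.quality_floor),
                cfg.noise_sd, sc["plausibility"].min, sc["plausibility"].max,
            )
            if plaus >= fw.plausibility_gate:
                spec = _likert(
                    rng,
                    _scale_map(q_eff, sc["specificity"].min,
                               sc["specificity"].max, True,
                               cfg.quality_floor),
                    cfg.noise_sd, sc["specificity"].min, sc["specificity"].max,
                )
        diagnoses.append(
            DiagnosisItem(
                diagnosis_text=cand_text, accuracy=acc,
                plausibility=plaus, specificity=spec,
            )
        )

    omission = _likert(
        rng, _scale_map(q, sc["omission"].min, sc["omission"].max, True,
                   cfg.quality_floor),
        cfg.noise_sd, sc["omission"].min, sc["omission"].max,
    )
    uncertainty = None
    if omission < sc["omission"].max:
        uncertainty = _likert(
            rng,
            _scale_map(q, sc["uncertainty"].min, sc["uncertainty"].max,
                       True, cfg.quality_floor),
            cfg.noise_sd, sc["uncertainty"].min, sc["uncertainty"].max,
        )

    n_sent = int(rng.integers(cfg.sentences_min, cfg.sentences_max + 1))
    sentences = []
    for k in range(n_sent):
        cui = cand_cuis[k % len(cand_cuis)]
        text = (
            f"the note supports {lexicon.primary_surface(cui)} given the "
            "documented findings"
        )
        # raw items: 1 = no evidence of a problem, so means fall with q
        vals = {
            comp: _likert(
                rng, _scale_map(q, 1, 5, False, cfg.quality_floor),
                cfg.noise_sd, 1, 5
            )
            for comp in ("comprehension", "rationale", "recall")
        }
        sentences.append(ReasoningSentenceItem(sentence_text=text, **vals))

    reasoning_omission = int(rng.random() < 0.25 * (1 - q))
    rec = RecordAnnotation(
        record_id=record_id,
        diagnoses=tuple(diagnoses),
        omission=omission,
        uncertainty=uncertainty,
        reasoning_sentences=tuple(sentences),
        reasoning_omission=reasoning_omission,
    )
    reasoning_raw = " . ".join(s.sentence_text for s in sentences)
    gen_row = {
        "record_id": record_id,
        "candidate_raw": " # ".join(cand_texts)
        + (f" <Reasoning> {reasoning_raw}" if reasoning_raw else ""),
        "reference_raw": " # ".join(ref_texts),
    }
    realized_overlap = n_keep / n_cand
    return gen_row, rec, realized_overlap


def generate_cohort(
    cfg: GeneratorConfig, fw: FrameworkConfig | None = None
) -> SyntheticCohort:
    """Full cohort under the ρ* coupling; deterministic for a fixed cfg."""
    rng = np.random.default_rng(cfg.seed)
    fw = fw or FrameworkConfig()
    lexicon = generate_lexicon(cfg)
    rho = cfg.latent_quality_corr

    q = rng.beta(cfg.quality_beta_a, cfg.quality_beta_b, size=cfg.n_records)
    # Gaussian copula: overlap propensity correlated rho* with q
    zq = stats.norm.ppf(
        stats.beta.cdf(q, cfg.quality_beta_a, cfg.quality_beta_b)
    )
    eps = rng.standard_normal(cfg.n_records)
    u = stats.norm.cdf(rho * zq + math.sqrt(max(0.0, 1 - rho**2)) * eps)

    records, gen_rows, truth_rows = [], [], []
    for i in range(cfg.n_records):
        rid = f"rec{i + 1:04d}"
        gen_row, rec, realized = generate_record(
            cfg, lexicon, float(q[i]), rid, rng, overlap=float(u[i]), fw=fw
        )
        records.append(rec)
        gen_rows.append(gen_row)
        truth_rows.append(
            {
                "record_id": rid,
                "q": float(q[i]),
                "overlap": realized,
                "rho_star": rho,
            }
        )
    return SyntheticCohort(
        records=records,
        generations=pd.DataFrame(gen_rows),
        truth=pd.DataFrame(truth_rows),
        lexicon=lexicon,
    )
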