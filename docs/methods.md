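# Methods

## The human evaluation instrument

A "record" is one model output for one progress note: an ordered
diagnosis list plus a free-text reasoning section.  The instrument
scores it in two branches.

**Diagnostic accuracy.**  Per diagnosis: Accuracy (1–5), Plausibility
(1–5) and Specificity (0–5).  The instrument branches: Plausibility is
asked only when the diagnosis is classified accurate, Specificity only
when it is classified plausible.  We take "classified accurate" to
mean Likert ≥ 4 (agree / strongly agree); the cut point is a
`FrameworkConfig` field (`accuracy_gate`, `plausibility_gate`).  Per
output: Omission (0–5, the scale maximum meaning nothing was omitted)
and, only when an omission occurred (omission below its maximum),
Uncertainty (0–5) — whether the omission reflects the model failing to
use information it was given rather than missing input.  Values the
branching skipped are imputed to 0 before averaging, so inaccurate
diagnoses still count in the denominators of the plausibility and
specificity means.

**Diagnostic reasoning.**  Per reasoning sentence: Comprehension,
Rationale and Recall, each 1–5 and worded so that 1 means *no evidence
of a problem*; they are inverted (x ↦ 6 − x) before averaging so
higher is uniformly better.  Per output: a binary reasoning-omission
item (explanation missing entirely).

**Composites.**  With p̄, s̄ the diagnosis-level means, ō the mean of
the two output-level accuracy items, and c̄, ē, ā the post-inversion
sentence-level means:

    D = (p̄ + s̄ + ō) / 15,    R = (c̄ + ē + ā) / 15

Each composite sums three components on a 0–5 span, hence the
denominator 15 and the (0, 1) range.  The pipeline order is fixed:
validate → impute → invert → average.

Consequences worth knowing:

* Because Uncertainty is gated out (and imputed to 0) exactly when
  nothing was omitted, a flawless record has ō = (5 + 0)/2 = 2.5 and
  D = 12.5/15 ≈ 0.833.  D = 1 is unreachable for a branching-compliant
  record; the [0, 1] bound is still the correct normalization of the
  formula.
* D is monotone in every single item value *within a fixed branch
  structure*.  Raising Omission to its maximum is not a single-value
  change — it removes the Uncertainty item — and can lower D when a
  high Uncertainty value is discarded.  The monotonicity tests
  therefore perturb values without crossing gates.
* The Accuracy item never enters D numerically; it acts only as the
  gate.  The binary reasoning-omission item is reported in the
  component frequency table but does not enter R (the composite lists
  only the three sentence components).  Binary items, where used, map
  onto the {0, 5} endpoints of the 0–5 scale.
* Records with zero reasoning sentences get R = NaN and are excluded
  from reasoning summaries (counted separately); records with zero
  diagnoses are scoreable only as explicit empty outputs, which carry
  no D.

The scale bounds above (which components are 0-based, the gate cut
points) are package defaults chosen from the instrument's structure;
all are configurable in `FrameworkConfig`.

## Automated metrics

All metrics compare a candidate text to a reference text at the record
level; multi-diagnosis lists are joined with a configurable separator
(default `" ; "`) before scoring, with per-diagnosis scoring available
by constructing pairs per list element.

* **ROUGE-L**: P = LCS/|cand|, R = LCS/|ref|, F with β = 1, over
  lowercased, punctuation-stripped, whitespace-split tokens.  The
  single-sequence LCS dialect (no union-LCS) is used because diagnosis
  lists are short.
* **Greedy-match F (BERTScore family)**: precision is the mean over
  candidate tokens of the maximum cosine similarity to any reference
  token; recall symmetrically; F is the harmonic mean.  No IDF
  weighting and no baseline rescaling by default (both are flags).
  Negative similarities are clipped at 0 before the harmonic mean so F
  stays in [0, 1].  Real clinical encoders (SapBERT-like,
  clinicalBERT-like, PubMedBERT-like) plug in through the
  `EmbeddingProvider` contract; the bundled providers are a one-hot
  provider (under which the metric reduces exactly to type-level token
  overlap — the main test oracle) and a deterministic hashed
  unit-vector provider (synthetic, no linguistic knowledge).
* **Concept F-score**: set precision/recall/F over concept identifiers
  returned by a `ConceptExtractor`.  The bundled extractor is greedy
  longest-match dictionary lookup against a surface→identifier
  lexicon; real UMLS access is an external adapter.
* **Graph-embedding F-score**: the greedy-match statistic applied to
  concept embeddings instead of token embeddings.  The aggregation of
  knowledge-graph-embedding scorers is not standardised; greedy
  matching is one defensible reading and is documented as such.
* **Log-probability score**: Σ log P(candidate tokens | reference)
  under a `ConditionalScorer` (higher is better, unbounded below).
  The bundled scorer is an add-α bigram model fit on the reference at
  call time; a uniform scorer gives the closed form n·log(1/V) used in
  tests.
* **Learned-regression metrics** (COMET/BLEURT-style) are never
  reimplemented; `ExternalRegressionAdapter` wraps any
  `(candidate, reference) → float` callable and is excluded from the
  default suite.

Conventions: any P or R with an empty denominator is reported as 0
(with a warning), F follows; cosine similarity with a zero vector
is 0; a configured metric whose backend is unavailable is skipped with
a warning, never silently zeroed.

## Meta-evaluation statistics

The unit of analysis is the record (one D, one metric value per
output).  For each metric and each human target (D or a component
mean) the report carries Spearman ρ, Pearson r, Kendall τ_b, their
95% CIs, p-values, and the Wilcoxon signed-rank p.

* Pearson CIs use the Fisher z transform with SE 1/√(n−3).
* Rank-correlation CIs default to a seeded percentile bootstrap (2,000
  resamples); a Fisher-z interval with adjusted variance
  (Bonett–Wright (1 + ρ²/2)/(n−3) for ρ, Fieller 0.437/(n−4) for τ)
  is available.  Every interval is tagged with its method.  No
  standard method yields intervals as narrow as some published
  rank-correlation CIs at n ≈ 186; both options here behave like
  textbook intervals.
* The Wilcoxon test discards zero differences, enumerates the exact
  sign-assignment null for n ≤ 12 (two-sided p doubles the smaller
  tail), and uses the normal approximation with continuity correction
  above that.  Because unbounded metrics make a paired location test
  against a [0, 1] human score meaningless, the metric is min-max
  rescaled to [0, 1] by default before pairing (`rescale=False` gives
  raw pairing).
* Comparing two metrics' correlations with the same human score uses
  Steiger's z for overlapping dependent correlations
  (Williams-type, with the back-transformed mean correlation in the
  covariance term); a seeded percentile bootstrap of the correlation
  difference is the cross-check.
* Cohen's kappa (unweighted, linear or quadratic) is reported against
  a 0.70 pass threshold, the conventional bar for adjudicated
  clinical annotation.  Two constant, identical raters make chance
  agreement 1 and kappa undefined; it is reported as 1 with a
  degenerate flag.
* p-values are reported raw by default (the reporting convention for
  this analysis); a Holm step-down adjustment is available as a flag.

## Synthetic cohort generator

The generator emulates the study shape so every module is testable
offline: 186 records, diagnoses per record ~ Uniform{3..5}, reasoning
sentences ~ Uniform{3..6}, a toy lexicon of 60 pseudoclinical concepts
with 1–3 surface variants each.

Per record: latent quality q ~ Beta(2, 2); an overlap propensity u is
coupled to q by a Gaussian copula with correlation ρ*
(`latent_quality_corr`), and the candidate list reproduces ≈ u of the
reference concepts, the remainder drawn uniformly from the rest of the
lexicon (hallucinations).  Likert items are drawn by discretizing a
normal (sd `noise_sd` = 0.8) around an affine map of q onto each
scale, with branching respected by construction.  Item means are
functions of q only — deliberately *not* of which candidates are
hallucinated — so that at ρ* = 0 the human composite is independent
of text overlap and recovered metric/human correlations are null; ρ*
is then the single ground-truth dial the recovery tests exercise.  The
response band has a baseline-competence floor (`quality_floor` = 0.55:
effective level = floor + (1 − floor)·q), reflecting cohorts in which
most generated diagnoses pass the accuracy and plausibility gates.

What the generator does **not** emulate: real clinical language, rater
disagreement, per-diagnosis correlation structure beyond q,
informative missingness, or any semantic relation between concepts
(embeddings of distinct toy concepts are near-orthogonal).  Passing
recovery tests therefore show that the pipeline measures the
correlation that is there, not that any particular metric aligns with
clinicians on real notes.

## Problem sizes and numerical choices

Default analysis sizes: cohorts of 186 records; bootstrap CIs at 2,000
resamples (500 in the summary script); type-I calibration at 1,000
null replicates; recovery at 10–20 seeds per coupling.  Exact Wilcoxon
switches to the normal approximation above n = 12 effective pairs.
Scores are kept at full float precision internally; CSV output uses a
deterministic `%.12g` format so repeated runs are byte-identical, and
run manifests record a SHA-256 hash per output plus the seed and a
hash of the analysis configuration (output paths excluded).

## Known limitations

* The scale anchors and zero-points are reconstructed defaults, not a
  transcription of the original survey wording.
* The graph-embedding scorer's aggregation is one interpretation of an
  underspecified metric family.
* The toy backends (hashed embeddings, bigram scorer, dictionary
  extractor) validate metric arithmetic and plumbing; conclusions
  about real clinical encoders require wiring real providers into the
  contracts.
* Reproducing any published cohort's actual score levels requires that
  study's notes, generations and raters; nothing here claims clinical
  validity of synthetic records.
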