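# dxeval

Human evaluation of LLM-generated medical diagnoses, and meta-evaluation
of how well automated text metrics track that human judgment.

When a language model summarises a progress note into a differential
diagnosis list, n-gram and embedding metrics may reward lexical overlap
rather than clinical quality. `dxeval` implements, end to end:

1. **A branched human evaluation instrument** for diagnosis generation.
   Each generated diagnosis is rated for Accuracy, Plausibility and
   Specificity on Likert scales, with survey branching — Plausibility is
   scored only for accurate diagnoses, Specificity only for plausible
   ones — plus output-level Omission and (conditional on an omission)
   Uncertainty.  Reasoning sentences are rated for Comprehension,
   Rationale and Recall.
2. **Composite scores per record** *i*:

       D_i = (p̄_i + s̄_i + ō_i) / 15        diagnostic accuracy ∈ [0, 1]
       R_i = (c̄_i + ē_i + ā_i) / 15        diagnostic reasoning ∈ [0, 1]

   where p̄, s̄ are means of plausibility and specificity over all
   diagnoses (values skipped by branching imputed to 0), ō is the mean
   of the omission and uncertainty items, and c̄, ē, ā are means of the
   reasoning items after the 6 − x inversion (raw items are worded so
   that 1 = no evidence of a problem).
3. **Automated metrics** over pluggable backends: ROUGE-L (LCS
   precision/recall/F), BERTScore-style greedy-matching F over token
   embeddings, concept-identifier F-score (CUI-style), greedy matching
   over knowledge-graph concept embeddings, and a BARTScore-style
   conditional log-probability.  Learned-regression metrics (COMET,
   BLEURT) are supported through an external-adapter contract only.
4. **Meta-evaluation statistics**: Spearman ρ, Pearson r and Kendall
   τ_b with confidence intervals (Fisher z for Pearson; seeded
   percentile bootstrap or adjusted Fisher z for the rank
   correlations), the paired Wilcoxon signed-rank test (exact null
   enumeration for small n), Steiger's z for comparing two metrics'
   correlations with the same human score, and Cohen's kappa for
   interrater agreement against a 0.70 threshold.
5. **A synthetic cohort generator** with a planted correlation ρ*
   between latent record quality and candidate/reference concept
   overlap, so the whole pipeline is testable without any clinical
   data.

Real study inputs (credentialed progress notes, model generations,
clinician annotations) cannot be distributed; the package ships only
synthetic data machinery that emulates the cohort shape (186 records,
3–5 diagnoses and 3–6 reasoning sentences per record).

## Worked example

Simulate an annotated cohort, score it, run the metric suite, and
correlate:

```sh
dxeval simulate --seed 7 --out cohort
dxeval score --annotations cohort/annotations.csv --out scored.csv
dxeval metrics --generations cohort/generations.tsv \
    --references cohort/references.tsv --lexicon cohort/lexicon.csv \
    --out metrics.csv
dxeval correlate --scored scored.csv --metrics metrics.csv --seed 7 \
    --out report.csv
```

The `score` step prints the cohort summary:

```
n=186 median D=0.582 (IQR 0.433-0.722) median R=0.806 (IQR 0.757-0.867)
```

i.e. the median record scores 0.582 of the maximum diagnostic-accuracy
composite and 0.806 on reasoning.  The correlation report
(`report.csv`) relates each metric to D:

```
           metric_name  spearman_rho  spearman_ci_low  spearman_ci_high  pearson_r  kendall_tau_b  wilcoxon_p
        concept_fscore         0.251            0.101             0.377      0.264          0.177       0.000
      embedding_fscore         0.238            0.091             0.366      0.240          0.157       0.000
graph_embedding_fscore         0.250            0.099             0.373      0.261          0.168       0.361
         logprob_score        -0.015           -0.172             0.137      0.002         -0.009       0.000
               rouge_l         0.247            0.098             0.381      0.247          0.171       0.000
```

This cohort was simulated with moderate quality/overlap coupling
(ρ* = 0.5), so the overlap-driven metrics correlate moderately with
human judgment while the toy log-probability metric, which does not
track concept overlap, sits near zero.  `dxeval run --indir cohort
--out results` chains the three stages and writes a manifest with a
SHA-256 hash of every output; re-running with the same seed reproduces
all files byte-identically.

The same commands work on real exports: a long-format annotation CSV
(`record_id, unit_type, unit_index, component, value`), generation
files with one `record_id<TAB>text` line per record in the
`#`-separated diagnosis dialect (reasoning section after
`<Reasoning>`), and any surface→identifier concept lexicon.

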