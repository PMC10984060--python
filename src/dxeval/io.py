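"""On-disk formats, the LLM-output dialect parser, and the pipeline.

Formats
-------
* Annotation CSV — long format, one row per scored unit item:
  ``record_id, unit_type ∈ {diagnosis, sentence, output}, unit_index,
  component, value``.  Free text lives in ``component == "text"`` rows;
  absent branched values are empty cells ("NA" also accepted).
* Annotation JSON — nested per-record objects; round-trips losslessly
  with the CSV.
* Generation text — one record per line, ``record_id<TAB>raw``.  The raw
  generation dialect separates diagnoses with ``#`` and starts the
  reasoning section at the first ``<Reasoning>`` marker.
* Scored CSV, metric CSV, correlation report CSV/JSON, truth CSV —
  plain tabular dumps with deterministic float formatting.
* Run manifest — JSON listing every output with a SHA-256 content hash,
  the seed, and a hash of the effective configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backends import BigramConditionalScorer, HashedEmbeddingProvider
from .framework import (
    DiagnosisItem,
    FrameworkConfig,
    RecordAnnotation,
    ReasoningSentenceItem,
    ScoredRecord,
    score_cohort,
)
from .meta import correlation_table
from .metrics import (
    MetricSuite,
    TextPair,
    concept_fscore,
    graph_embedding_fscore,
    greedy_match_fscore,
    logprob_score,
    rouge_l,
    run_metric_suite,
)

logger = logging.getLogger(__name__)

__all__ = [
    "parse_generation",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_annotations_json",
    "write_annotations_json",
    "read_generations",
    "write_generations",
    "write_scored_csv",
    "read_scored_csv",
    "default_metric_suite",
    "RunConfig",
    "run_pipeline",
]

_FLOAT_FMT = "%.12g"
_ABSENT = {"", "na", "nan", "none"}

REASONING_MARKER = "<Reasoning>"
DIAGNOSIS_SEPARATOR = "#"


def parse_generation(
    raw: str, warn_missing_marker: bool = True
) -> tuple[list[str], str]:
    """Split one raw generation into (diagnosis list, reasoning text).

    Text before the first ``<Reasoning>`` marker is split on ``#``,
    trimmed, empty segments dropped.  Everything after the marker
    (marker stripped) is the reasoning text; later markers are plain
    reasoning content.  A missing marker parses the whole string as
    diagnoses with a logged warning.
    """
    if raw is None or not raw.strip():
        raise ValueError("empty generation text")
    head, marker, tail = raw.partition(REASONING_MARKER)
    if not marker and warn_missing_marker:
        logger.warning("generation has no %s marker", REASONING_MARKER)
    diagnoses = [
        seg.strip()
        for seg in head.split(DIAGNOSIS_SEPARATOR)
        if seg.strip()
    ]
    return diagnoses, tail.strip()


# ---------------------------------------------------------------------------
# annotation round-trip


def _rows_for_record(rec: RecordAnnotation) -> list[dict]:
    rows = []

    def add(unit_type, unit_index, component, value):
        rows.append(
            {
                "record_id": rec.record_id,
                "unit_type": unit_type,
                "unit_index": unit_index,
                "component": component,
                "value": "" if value is None else value,
            }
        )

    for i, d in enumerate(rec.diagnoses):
        add("diagnosis", i, "text", d.diagnosis_text)
        add("diagnosis", i, "accuracy", d.accuracy)
        add("diagnosis", i, "plausibility", d.plausibility)
        add("diagnosis", i, "specificity", d.specificity)
    for i, s in enumerate(rec.reasoning_sentences):
        add("sentence", i, "text", s.sentence_text)
        add("sentence", i, "comprehension", s.comprehension)
        add("sentence", i, "rationale", s.rationale)
        add("sentence", i, "recall", s.recall)
    add("output", 0, "omission", rec.omission)
    add("output", 0, "uncertainty", rec.uncertainty)
    add("output", 0, "reasoning_omission", rec.reasoning_omission)
    add("output", 0, "empty_output", int(rec.empty_output))
    return rows


def write_annotations_csv(
    records: Sequence[RecordAnnotation], path: str | Path
) -> None:
    rows = [r for rec in records for r in _rows_for_record(rec)]
    pd.DataFrame(
        rows,
        columns=["record_id", "unit_type", "unit_index", "component", "value"],
    ).to_csv(path, index=False)


def _parse_value(v) -> int | None:
    if v is None:
        return None
    s = str(v).strip()
    if s.lower() in _ABSENT:
        return None
    return int(float(s))


def read_annotations_csv(path: str | Path) -> list[RecordAnnotation]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"record_id", "unit_type", "unit_index", "component", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns {sorted(missing)}")
    records = []
    for rid, grp in df.groupby("record_id", sort=False):
        records.append(_record_from_rows(rid, grp))
    return records


def _record_from_rows(rid: str, grp: pd.DataFrame) -> RecordAnnotation:
    diags: dict[int, dict] = {}
    sents: dict[int, dict] = {}
    output: dict[str, str] = {}
    for _, row in grp.iterrows():
        unit, comp, val = row["unit_type"], row["component"], row["value"]
        if unit == "diagnosis":
            diags.setdefault(int(row["unit_index"]), {})[comp] = val
        elif unit == "sentence":
            sents.setdefault(int(row["unit_index"]), {})[comp] = val
        elif unit == "output":
            output[comp] = val
        else:
            raise ValueError(f"record {rid}: unknown unit_type {unit!r}")

    diagnoses = tuple(
        DiagnosisItem(
            diagnosis_text=d.get("text", ""),
            accuracy=_parse_value(d.get("accuracy")),
            plausibility=_parse_value(d.get("plausibility")),
            specificity=_parse_value(d.get("specificity")),
        )
        for _, d in sorted(diags.items())
    )
    sentences = tuple(
        ReasoningSentenceItem(
            sentence_text=s.get("text", ""),
            comprehension=_parse_value(s.get("comprehension")),
            rationale=_parse_value(s.get("rationale")),
            recall=_parse_value(s.get("recall")),
        )
        for _, s in sorted(sents.items())
    )
    return RecordAnnotation(
        record_id=str(rid),
        diagnoses=diagnoses,
        omission=_parse_value(output.get("omission")),
        uncertainty=_parse_value(output.get("uncertainty")),
        reasoning_sentences=sentences,
        reasoning_omission=_parse_value(output.get("reasoning_omission")) or 0,
        empty_output=bool(_parse_value(output.get("empty_output")) or 0),
    )


def write_annotations_json(
    records: Sequence[RecordAnnotation], path: str | Path
) -> None:
    payload = [dataclasses.asdict(rec) for rec in records]
    for rec in payload:
        rec.pop("reasoning_inverted", None)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_annotations_json(path: str | Path) -> list[RecordAnnotation]:
    payload = json.loads(Path(path).read_text())
    records = []
    for rec in payload:
        records.append(
            RecordAnnotation(
                record_id=rec["record_id"],
                diagnoses=tuple(
                    DiagnosisItem(**d) for d in rec["diagnoses"]
                ),
                omission=rec["omission"],
                uncertainty=rec.get("uncertainty"),
                reasoning_sentences=tuple(
                    ReasoningSentenceItem(**s)
                    for s in rec["reasoning_sentences"]
                ),
                reasoning_omission=rec.get("reasoning_omission", 0),
                empty_output=rec.get("empty_output", False),
            )
        )
    return records


# ---------------------------------------------------------------------------
# generation text + tabular outputs


def write_generations(
    table: pd.DataFrame, path: str | Path, column: str
) -> None:
    """One ``record_id<TAB>text`` line per record."""
    lines = [
        f"{row.record_id}\t{getattr(row, column)}"
        for row in table.itertuples(index=False)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_generations(path: str | Path) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        if "\t" not in line:
            raise ValueError(f"{path}:{lineno}: expected record_id<TAB>text")
        rid, text = line.split("\t", 1)
        rows.append({"record_id": rid, "text": text})
    return pd.DataFrame(rows)


SCORED_COLUMNS = [
    "record_id", "p_bar", "s_bar", "o_bar", "c_bar", "e_bar", "a_bar",
    "D", "R",
]


def write_scored_csv(
    scored: Sequence[ScoredRecord], path: str | Path
) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in scored])
    df[SCORED_COLUMNS].to_csv(
        path, index=False, float_format=_FLOAT_FMT, na_rep="NA"
    )


def read_scored_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"])


def write_table_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="NA")


# ---------------------------------------------------------------------------
# metric suite wiring


def hashed_concept_embedder(dim: int = 32):
    """Deterministic unit-vector embedding of concept identifiers."""
    provider = HashedEmbeddingProvider(dim=dim)

    def embed(cui: str) -> np.ndarray:
        return provider.embed([cui])[0]

    return embed


def default_metric_suite(
    lexicon_surface_map: dict[str, str] | None = None,
    embedding_dim: int = 64,
    join_separator: str = " ; ",
) -> MetricSuite:
    """Bundled offline suite over the toy backends.

    Concept-based metrics need a surface→identifier lexicon; without one
    they are skipped with a warning (never silently zeroed).
    """
    from .backends import DictionaryConceptExtractor

    suite = MetricSuite()
    suite.register("rouge_l", rouge_l)
    provider = HashedEmbeddingProvider(dim=embedding_dim)
    suite.register(
        "embedding_fscore",
        lambda pair: greedy_match_fscore(pair, provider, "embedding_fscore"),
    )
    scorer = BigramConditionalScorer()
    suite.register("logprob_score", lambda pair: logprob_score(pair, scorer))
    if lexicon_surface_map:
        extractor = DictionaryConceptExtractor(lexicon_surface_map)
        embedder = hashed_concept_embedder()
        suite.register(
            "concept_fscore", lambda pair: concept_fscore(pair, extractor)
        )
        suite.register(
            "graph_embedding_fscore",
            lambda pair: graph_embedding_fscore(pair, extractor, embedder),
        )
    else:
        logger.warning(
            "no concept lexicon configured; skipping concept_fscore and "
            "graph_embedding_fscore"
        )
    return suite


def pairs_from_generations(
    generations: pd.DataFrame,
    references: pd.DataFrame,
    join_separator: str = " ; ",
) -> list[TextPair]:
    """Build record-level TextPairs from raw generation/reference tables.

    Candidate diagnosis lists are parsed from the ``#`` dialect and
    joined into one text per record; references likewise.
    """
    ref_map = dict(zip(references["record_id"], references["text"]))
    pairs = []
    for row in generations.itertuples(index=False):
        if row.record_id not in ref_map:
            raise KeyError(f"no reference for record {row.record_id}")
        cand_diags, _reasoning = parse_generation(row.text)
        # references are plain diagnosis lists; no reasoning section expected
        ref_diags, _ = parse_generation(
            ref_map[row.record_id], warn_missing_marker=False
        )
        pairs.append(
            TextPair(
                pair_id=row.record_id,
                candidate=join_separator.join(cand_diags),
                reference=join_separator.join(ref_diags),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class RunConfig:
    """Paths and knobs for one end-to-end run."""

    annotations: Path
    generations: Path
    references: Path
    outdir: Path
    lexicon: Path | None = None
    seed: int = 0
    components: tuple[str, ...] = ("D",)
    metrics: tuple[str, ...] | None = None
    ci_method: str = "bootstrap"
    n_resamples: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        def p(key, default=None):
            v = raw.get(key, default)
            return (base / v) if v is not None else None
        return cls(
            annotations=p("annotations"),
            generations=p("generations"),
            references=p("references"),
            outdir=p("outdir", "out"),
            lexicon=p("lexicon"),
            seed=int(raw.get("seed", 0)),
            components=tuple(raw.get("components", ["D"])),
            metrics=tuple(raw["metrics"]) if "metrics" in raw else None,
            ci_method=raw.get("ci_method", "bootstrap"),
            n_resamples=int(raw.get("n_resamples", 2000)),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {
            k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, fw: FrameworkConfig | None = None) -> dict:
    """score → metrics → correlate, with a hashed run manifest.

    Re-running with identical inputs and seed reproduces every output
    byte-identically (no timestamps enter any file).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        records = read_annotations_csv(cfg.annotations)
        scored, summary = score_cohort(records, fw)
        scored_path = outdir / "scored.csv"
        write_scored_csv(scored, scored_path)
        written.append(scored_path)

        lex_map = None
        if cfg.lexicon is not None:
            lex_df = pd.read_csv(cfg.lexicon)
            lex_map = dict(zip(lex_df["surface"], lex_df["cui"]))
        suite = default_metric_suite(lex_map)
        pairs = pairs_from_generations(
            read_generations(cfg.generations),
            read_generations(cfg.references),
        )
        requested = list(cfg.metrics) if cfg.metrics else list(suite.metrics)
        available = [m for m in requested if m in suite.metrics]
        skipped = sorted(set(requested) - set(available))
        for name in skipped:
            logger.warning("metric %s has no backend; skipped", name)
        metric_df = run_metric_suite(pairs, suite, metrics=available)
        metrics_path = outdir / "metrics.csv"
        write_table_csv(metric_df, metrics_path)
        written.append(metrics_path)

        scored_df = pd.DataFrame([dataclasses.asdict(s) for s in scored])
        report = correlation_table(
            scored_df, metric_df, components=cfg.components,
            seed=cfg.seed, ci_method=cfg.ci_method,
            n_resamples=cfg.n_resamples,
        )
        report_csv = outdir / "correlations.csv"
        write_table_csv(report, report_csv)
        written.append(report_csv)
        report_json = outdir / "correlations.json"
        report_json.write_text(
            json.dumps(report.to_dict(orient="records"), indent=2,
                       sort_keys=True, allow_nan=True)
        )
        written.append(report_json)

        summary_json = outdir / "summary.json"
        summary_json.write_text(
            json.dumps(
                {
                    "n_records": summary.n_records,
                    "n_diagnoses": summary.n_diagnoses,
                    "n_sentences": summary.n_sentences,
                    "median_D": summary.median_D,
                    "iqr_D": list(summary.iqr_D),
                    "median_R": summary.median_R,
                    "iqr_R": list(summary.iqr_R),
                    "n_records_with_reasoning":
                        summary.n_records_with_reasoning,
                },
                indent=2, sort_keys=True,
            )
        )
        written.append(summary_json)

        cfg_dict = cfg.to_dict()
        cfg_dict.pop("outdir")  # output location is not analysis config
        cfg_blob = json.dumps(cfg_dict, sort_keys=True).encode()
        manifest = {
            "package": "dxeval",
            "version": __version__,
            "seed": cfg.seed,
            "config_sha256": hashlib.sha256(cfg_blob).hexdigest(),
            "skipped_metrics": skipped,
            "outputs": {
                p.name: _sha256(p) for p in sorted(written)
            },
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
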