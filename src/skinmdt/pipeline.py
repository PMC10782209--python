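"""End-to-end pipeline: generate -> extract -> decide -> letters -> evaluate.

Every stage reads its inputs from disk artifacts written by the previous
stage, so any prefix of the pipeline can be rerun or replaced by external
data.  Rerunning an unchanged config reproduces byte-identical data
artifacts (the run manifest's timings aside).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .corpus import (
    GenerationConfig,
    generate_corpus,
    read_corpus_csv,
    write_corpus,
)
from .decision import (
    aggregate_recommendation,
    decisions_to_rows,
    generate_letter,
)
from .extraction import GazetteerSet, assemble_records
from .evaluation import evaluate_run
from .labels import CLASS_LABELS, DEFAULT_PRECEDENCE, Recommendation
from .records import LesionRecord

logger = logging.getLogger(__name__)

STAGES = ("generate", "extract", "decide", "letters", "evaluate")


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""


@dataclass
class PipelineConfig:
    out_dir: str
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    n_patients: int = 50
    noise_level: float = 0.0
    corpus_csv: Optional[str] = None  # external corpus when not generating
    gold_csv: Optional[str] = None
    gazetteer_dir: Optional[str] = None
    precedence: Optional[list[str]] = None  # recommendation labels, high->low
    log_level: str = "info"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        self.stages = [s for s in STAGES if s in self.stages]

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "stages": list(self.stages),
            "seed": self.seed,
            "n_patients": self.n_patients,
            "noise_level": self.noise_level,
            "corpus_csv": self.corpus_csv,
            "gold_csv": self.gold_csv,
            "gazetteer_dir": self.gazetteer_dir,
            "precedence": self.precedence,
            "log_level": self.log_level,
        }

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text("utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def resolved_precedence(self) -> Sequence[Recommendation]:
        if self.precedence is None:
            return DEFAULT_PRECEDENCE
        return [Recommendation(p) for p in self.precedence]


EXTRACTION_FIELDS = ("patient_id", "report_id", *LesionRecord.CSV_FIELDS)


def write_extractions_csv(path, rows: list[dict]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=EXTRACTION_FIELDS)
        writer.writeheader()
        writer.writerows(rows)


def read_extractions_csv(path) -> dict[str, list[LesionRecord]]:
    """Extraction rows grouped per patient, in file order."""
    grouped: dict[str, list[LesionRecord]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            grouped.setdefault(row["patient_id"], []).append(
                LesionRecord.from_row(row)
            )
    return grouped


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gazetteers = (
        GazetteerSet.from_directory(config.gazetteer_dir)
        if config.gazetteer_dir
        else None
    )
    timings: dict[str, float] = {}
    manifest: dict = {
        "pipeline_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages_run": [],
    }

    corpus_csv = Path(config.corpus_csv) if config.corpus_csv else out / "corpus.csv"
    gold_csv = Path(config.gold_csv) if config.gold_csv else out / "gold.csv"
    extractions_csv = out / "extractions.csv"
    decisions_csv = out / "decisions.csv"

    for stage in config.stages:
        start = time.perf_counter()
        try:
            if stage == "generate":
                gen = GenerationConfig(
                    n_patients=config.n_patients,
                    noise_level=config.noise_level,
                    seed=config.seed,
                )
                write_corpus(generate_corpus(gen), out)
            elif stage == "extract":
                reports = read_corpus_csv(corpus_csv)
                rows = []
                for report in reports:
                    for record in assemble_records(report, gazetteers):
                        rows.append(
                            {
                                "patient_id": report.patient_id,
                                "report_id": report.report_id,
                                **record.to_row(),
                            }
                        )
                write_extractions_csv(extractions_csv, rows)
            elif stage == "decide":
                grouped = read_extractions_csv(extractions_csv)
                decisions = [
                    aggregate_recommendation(
                        records, patient_id=pid,
                        precedence=config.resolved_precedence(),
                    )
                    for pid, records in grouped.items()
                ]
                with open(decisions_csv, "w", newline="", encoding="utf-8") as fh:
                    writer = csv.DictWriter(
                        fh, fieldnames=("patient_id", "recommendation", "rule_ids")
                    )
                    writer.writeheader()
                    writer.writerows(decisions_to_rows(decisions))
            elif stage == "letters":
                grouped = read_extractions_csv(extractions_csv)
                letters_dir = out / "letters"
                letters_dir.mkdir(exist_ok=True)
                for pid, records in grouped.items():
                    decision = aggregate_recommendation(
                        records, patient_id=pid,
                        precedence=config.resolved_precedence(),
                    )
                    letter = generate_letter(
                        decision,
                        {
                            "patient_name": f"Patient {pid}",
                            "clinic_name": "Dermatology Surgery Service",
                        },
                        records=records,
                    )
                    (letters_dir / f"{pid}.txt").write_text(letter, encoding="utf-8")
            elif stage == "evaluate":
                gold = _read_column(gold_csv, "expected_recommendation", "patient_id")
                with open(decisions_csv, newline="", encoding="utf-8") as fh:
                    predicted = {
                        row["patient_id"]: row["recommendation"]
                        for row in csv.DictReader(fh)
                    }
                ids = [pid for pid in gold if pid in predicted]
                missing = [pid for pid in gold if pid not in predicted]
                if missing:
                    raise PipelineError(
                        f"{len(missing)} gold patients lack predictions "
                        f"(first: {missing[0]})"
                    )
                evaluate_run(
                    [gold[pid] for pid in ids],
                    [predicted[pid] for pid in ids],
                    CLASS_LABELS,
                    out_dir=out,
                )
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        timings[stage] = time.perf_counter() - start
        manifest["stages_run"].append(stage)

    manifest["stage_seconds"] = timings
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest


def _read_column(path, column: str, key: str) -> dict[str, str]:
    values: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            values.setdefault(row[key], row[column])
    return values
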