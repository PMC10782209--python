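"""Toy cohort filter emulating the EHR query that selects surgically
managed patients by coded diagnosis (SNOMED-style codes, simulated)."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence


class CohortConfigError(ValueError):
    pass


#: Simulated SNOMED-style codes for BCC used by the synthetic cohort.
DEFAULT_BCC_CODES = frozenset({"M-80903", "M-80913", "M-80923", "M-80973"})


@dataclass
class CohortRecord:
    patient_id: str
    report_id: str
    coded_diagnoses: list[str] = field(default_factory=list)
    management: str = "surgery"  # surgery | non_surgical

    def __post_init__(self) -> None:
        if not self.patient_id or not self.report_id:
            raise CohortConfigError("patient_id and report_id must be nonempty")
        if self.management not in ("surgery", "non_surgical"):
            raise CohortConfigError(f"unknown management {self.management!r}")


def filter_cohort(
    records: Sequence[CohortRecord],
    bcc_code_set: Iterable[str] = DEFAULT_BCC_CODES,
    surgical_only: bool = True,
) -> list[CohortRecord]:
    """Keep records carrying a BCC code (and, optionally, surgical
    management), preserving input order."""
    codes = set(bcc_code_set)
    if not codes:
        raise CohortConfigError("bcc_code_set must be nonempty")
    out = []
    for record in records:
        if not codes.intersection(record.coded_diagnoses):
            continue
        if surgical_only and record.management != "surgery":
            continue
        out.append(record)
    return out


def read_cohort_csv(path) -> list[CohortRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                CohortRecord(
                    patient_id=row["patient_id"],
                    report_id=row["report_id"],
                    coded_diagnoses=[
                        c for c in row.get("coded_diagnoses", "").split(";") if c
                    ],
                    management=row.get("management", "surgery"),
                )
            )
    return records
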