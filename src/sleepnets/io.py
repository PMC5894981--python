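"""Reading and writing the canonical hypnogram / metadata formats.

Hypnogram CSV: header ``epoch,stage``, one row per 30-s epoch, 0-based
consecutive epoch indices, stage codes from the raw alphabet
(W, N1, N2, N3, S3, S4, R, MOV, UNS) or the canonical one.

Metadata TSV: one row per (subject, night) with demographics, respiratory
indices, lights-off clock time and scoring standard; empty numeric cells
mean "missing", never zero.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .stages import (CANONICAL_STAGES, format_clock, map_raw_stages,
                     parse_clock)

METADATA_COLUMNS = [
    "subject_id", "dataset_id", "night_index", "age", "sex", "bmi",
    "lights_off_clock", "ahi", "oahi", "oai", "cai", "rdi", "scoring",
    "disorder_flag", "medication_flag",
]

_MANDATORY = ["subject_id", "dataset_id", "age", "sex"]

logger = logging.getLogger(__name__)


@dataclass
class Hypnogram:
    """An epoch-coded stage sequence with its clock anchor and identity.

    ``stages`` holds string labels — raw codes on ingest, canonical after
    :func:`map_stage_codes`.  ``onset_clock`` (minutes since noon) is set by
    ``preprocess.trim_wake`` once pre-onset wake is removed; before that it
    equals ``lights_off_clock``.
    """

    subject_id: str
    dataset_id: str
    stages: list[str]
    epoch_seconds: float = 30.0
    lights_off_clock: float = 0.0  # minutes since 12:00 noon
    night_index: int = 1
    onset_clock: float | None = None
    canonical: bool = False

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("empty hypnogram")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def epoch_minutes(self) -> float:
        return self.epoch_seconds / 60.0

    @property
    def duration_minutes(self) -> float:
        return self.n_epochs * self.epoch_minutes

    def key(self) -> tuple[str, int]:
        return (self.subject_id, self.night_index)

    def replace(self, **changes) -> "Hypnogram":
        return dataclasses.replace(self, **changes)


@dataclass
class SubjectRecord:
    subject_id: str
    dataset_id: str
    age: float
    sex: str  # 'F' or 'M'
    night_index: int = 1
    bmi: float | None = None
    lights_off_clock: float | None = None  # minutes since noon
    ahi: float | None = None
    oahi: float | None = None
    oai: float | None = None
    cai: float | None = None
    rdi: float | None = None
    scoring: str = "RK"
    disorder_flag: bool = False
    medication_flag: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"invalid sex {self.sex!r}")
        for name in ("age", "bmi", "ahi", "oahi", "oai", "cai", "rdi"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Cohort:
    """Hypnograms keyed by (subject_id, night_index) plus subject metadata."""

    hypnograms: dict[tuple[str, int], Hypnogram] = field(default_factory=dict)
    subjects: dict[str, SubjectRecord] = field(default_factory=dict)

    def add(self, hyp: Hypnogram, record: SubjectRecord | None = None) -> None:
        if record is not None:
            self.subjects[record.subject_id] = record
        if hyp.subject_id not in self.subjects:
            raise ValueError(f"unknown subject {hyp.subject_id!r}")
        self.hypnograms[hyp.key()] = hyp

    @property
    def dataset_ids(self) -> list[str]:
        return sorted({r.dataset_id for r in self.subjects.values()})

    def __len__(self) -> int:
        return len(self.hypnograms)

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        keep = set(subject_ids)
        return Cohort(
            hypnograms={k: h for k, h in self.hypnograms.items() if h.subject_id in keep},
            subjects={s: r for s, r in self.subjects.items() if s in keep},
        )


def _as_lines(stream) -> Iterable[str]:
    if isinstance(stream, (str, Path)):
        return Path(stream).read_text().splitlines()
    return stream.read().splitlines()


def read_hypnogram_csv(stream, metadata: SubjectRecord,
                       epoch_seconds: float = 30.0) -> Hypnogram:
    """Parse a hypnogram CSV (header ``epoch,stage``) into a raw Hypnogram.

    Raw stage codes are preserved; call :func:`map_stage_codes` to
    harmonise.  Epoch indices must be 0-based and consecutive.
    """
    lines = [ln for ln in _as_lines(stream) if ln.strip()]
    if not lines or lines[0].strip().lower().replace(" ", "") != "epoch,stage":
        raise ValueError("hypnogram CSV must start with header 'epoch,stage'")
    if len(lines) == 1:
        raise ValueError("empty hypnogram")
    stages: list[str] = []
    valid = set(map_raw_tokens())
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'epoch,stage'")
        idx_s, tok = parts[0].strip(), parts[1].strip()
        try:
            idx = int(idx_s)
        except ValueError:
            raise ValueError(f"line {lineno}: bad epoch index {idx_s!r}") from None
        if idx != len(stages):
            raise ValueError(f"gap in epoch index at line {lineno} (got {idx})")
        if tok not in valid:
            raise ValueError(f"unknown stage code {tok!r} at line {lineno}")
        stages.append(tok)
    return Hypnogram(
        subject_id=metadata.subject_id,
        dataset_id=metadata.dataset_id,
        stages=stages,
        epoch_seconds=epoch_seconds,
        lights_off_clock=metadata.lights_off_clock or 0.0,
        night_index=metadata.night_index,
    )


def map_raw_tokens() -> tuple[str, ...]:
    """All stage tokens accepted in hypnogram files (raw + canonical)."""
    return ("W", "N1", "N2", "N3", "S3", "S4", "R", "MOV", "UNS") + CANONICAL_STAGES


def write_hypnogram_csv(hyp: Hypnogram, stream) -> None:
    buf = ["epoch,stage"]
    buf += [f"{i},{s}" for i, s in enumerate(hyp.stages)]
    text = "\n".join(buf) + "\n"
    if isinstance(stream, (str, Path)):
        Path(stream).write_text(text)
    else:
        stream.write(text)


def map_stage_codes(hyp: Hypnogram) -> Hypnogram:
    """Harmonise a hypnogram to the canonical 5-stage alphabet.

    Idempotent on canonical input.  MOV/UNS epochs are recoded to the
    neighbouring stage (see :func:`sleepnets.stages.map_raw_stages`).
    """
    canon, n_recoded = map_raw_stages(hyp.stages)
    if n_recoded:
        logger.info("recoded %d MOV/UNS epochs for %s night %d",
                    n_recoded, hyp.subject_id, hyp.night_index)
    return hyp.replace(stages=canon, canonical=True)


def _parse_float(cell: str, what: str, row: int) -> float | None:
    cell = cell.strip()
    if cell == "" or cell.upper() in ("NA", "NAN"):
        return None
    try:
        v = float(cell)
    except ValueError:
        raise ValueError(f"row {row}: invalid {what} {cell!r}") from None
    if math.isnan(v):
        return None
    return v


def _parse_bool(cell: str) -> bool:
    return cell.strip().lower() in ("1", "true", "yes", "y")


def read_metadata_table(stream) -> list[SubjectRecord]:
    """Parse the subject metadata TSV into SubjectRecords.

    Missing BMI / respiratory cells become ``None`` (missing), never zero.
    """
    lines = [ln for ln in _as_lines(stream) if ln.strip()]
    if not lines:
        raise ValueError("empty metadata table")
    header = [h.strip() for h in lines[0].split("\t")]
    for col in _MANDATORY:
        if col not in header:
            raise ValueError(f"missing column {col!r}")
    col = {name: i for i, name in enumerate(header)}

    def get(parts: list[str], name: str) -> str:
        i = col.get(name)
        return parts[i] if i is not None and i < len(parts) else ""

    records: list[SubjectRecord] = []
    for row, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        age = _parse_float(get(parts, "age"), "age", row)
        if age is None:
            raise ValueError(f"row {row}: invalid age ''")
        sex = get(parts, "sex").strip().upper()
        if sex not in ("F", "M"):
            raise ValueError(f"row {row}: invalid sex {sex!r}")
        clock_cell = get(parts, "lights_off_clock").strip()
        clock = parse_clock(clock_cell) if clock_cell else None
        night_cell = get(parts, "night_index").strip()
        records.append(SubjectRecord(
            subject_id=get(parts, "subject_id").strip(),
            dataset_id=get(parts, "dataset_id").strip(),
            night_index=int(night_cell) if night_cell else 1,
            age=age,
            sex=sex,
            bmi=_parse_float(get(parts, "bmi"), "bmi", row),
            lights_off_clock=clock,
            ahi=_parse_float(get(parts, "ahi"), "ahi", row),
            oahi=_parse_float(get(parts, "oahi"), "oahi", row),
            oai=_parse_float(get(parts, "oai"), "oai", row),
            cai=_parse_float(get(parts, "cai"), "cai", row),
            rdi=_parse_float(get(parts, "rdi"), "rdi", row),
            scoring=get(parts, "scoring").strip() or "RK",
            disorder_flag=_parse_bool(get(parts, "disorder_flag")),
            medication_flag=_parse_bool(get(parts, "medication_flag")),
        ))
    return records


def write_metadata_table(records: Iterable[SubjectRecord], stream) -> None:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "dataset_id": r.dataset_id,
            "night_index": r.night_index,
            "age": r.age,
            "sex": r.sex,
            "bmi": "" if r.bmi is None else r.bmi,
            "lights_off_clock": "" if r.lights_off_clock is None
                                 else format_clock(r.lights_off_clock),
            "ahi": "" if r.ahi is None else r.ahi,
            "oahi": "" if r.oahi is None else r.oahi,
            "oai": "" if r.oai is None else r.oai,
            "cai": "" if r.cai is None else r.cai,
            "rdi": "" if r.rdi is None else r.rdi,
            "scoring": r.scoring,
            "disorder_flag": int(r.disorder_flag),
            "medication_flag": int(r.medication_flag),
        })
    df = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    if isinstance(stream, (str, Path)):
        df.to_csv(stream, sep="\t", index=False)
    else:
        df.to_csv(stream, sep="\t", index=False)


def read_cohort(hypnogram_dir, metadata_path) -> Cohort:
    """Load a cohort from a directory of ``<subject>_<night>.csv`` files and
    a metadata TSV."""
    records = read_metadata_table(metadata_path)
    cohort = Cohort(subjects={r.subject_id: r for r in records})
    root = Path(hypnogram_dir)
    for r in records:
        path = root / f"{r.subject_id}_{r.night_index}.csv"
        if not path.exists():
            continue
        cohort.add(read_hypnogram_csv(path, r))
    return cohort


def write_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_metadata_table(cohort.subjects.values(), out / "subjects.tsv")
    for hyp in cohort.hypnograms.values():
        write_hypnogram_csv(hyp, out / f"{hyp.subject_id}_{hyp.night_index}.csv")
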