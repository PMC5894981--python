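"""Traditional per-record sleep summaries.

Computed on the trimmed canonical record (the same sequence the dynamic
pipeline uses).  Time in bed after onset runs from sleep onset to the last
sleep epoch, so WASO minutes exclude the terminal awakening — consistent
with the dynamics modules, which never treat final wake as an outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import Hypnogram
from .stages import CANONICAL_STAGES, SLEEP_STAGES


@dataclass
class StaticSummary:
    subject_id: str
    total_sleep_time: float           # minutes in S1+S2+SWS+REM
    time_in_bed_after_onset: float    # onset .. last sleep epoch, minutes
    sleep_efficiency: float           # TST / time in bed after onset
    rem_latency: float | None         # minutes onset -> first REM; None if no REM
    minutes_in_stage: dict[str, float]
    stage_proportions: dict[str, float]  # minutes / TST, sleep stages only
    sleep_onset_clock: float          # minutes since noon


def compute_static_summary(hyp: Hypnogram) -> StaticSummary:
    """Summarise a trimmed canonical hypnogram.

    Stage proportions are minutes in each sleep stage normalised by total
    sleep time; REM latency is undefined (None) for a REM-free record.
    """
    if not hyp.canonical:
        raise ValueError("compute_static_summary requires a canonical hypnogram")
    if not hyp.stages:
        raise ValueError("empty record")
    if hyp.stages[0] == "WASO":
        raise ValueError("record not trimmed (starts with WASO)")
    em = hyp.epoch_minutes
    last_sleep = max(i for i, s in enumerate(hyp.stages) if s != "WASO")
    in_bed_epochs = hyp.stages[: last_sleep + 1]
    minutes = {s: 0.0 for s in CANONICAL_STAGES}
    for s in in_bed_epochs:
        minutes[s] += em
    tst = sum(minutes[s] for s in SLEEP_STAGES)
    in_bed = len(in_bed_epochs) * em
    first_rem = next((i for i, s in enumerate(hyp.stages) if s == "REM"), None)
    onset = hyp.onset_clock if hyp.onset_clock is not None else hyp.lights_off_clock
    return StaticSummary(
        subject_id=hyp.subject_id,
        total_sleep_time=tst,
        time_in_bed_after_onset=in_bed,
        sleep_efficiency=tst / in_bed,
        rem_latency=None if first_rem is None else first_rem * em,
        minutes_in_stage=minutes,
        stage_proportions={s: minutes[s] / tst for s in SLEEP_STAGES} if tst > 0 else {},
        sleep_onset_clock=onset,
    )


def summaries_table(summaries: list[StaticSummary]) -> pd.DataFrame:
    """One row per record; suitable for TSV export."""
    rows = []
    for s in summaries:
        row = {
            "subject_id": s.subject_id,
            "tst_min": s.total_sleep_time,
            "time_in_bed_after_onset_min": s.time_in_bed_after_onset,
            "sleep_efficiency": s.sleep_efficiency,
            "rem_latency_min": s.rem_latency,
            "sleep_onset_clock_min": s.sleep_onset_clock,
        }
        for st in CANONICAL_STAGES:
            row[f"min_{st}"] = s.minutes_in_stage[st]
        for st in SLEEP_STAGES:
            row[f"prop_{st}"] = s.stage_proportions.get(st)
        rows.append(row)
    return pd.DataFrame(rows)
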