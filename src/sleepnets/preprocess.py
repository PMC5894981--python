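"""Hypnogram preprocessing: exclusion screening, pre-onset wake trimming,
ordered gap-closing smoothing, and bout extraction.

The smoothing rule closes, for REM then SWS then Stage 2 in that order,
interior gaps of up to one minute of any other stage lying strictly between
two runs of the target stage.  On interior gaps this run-length gap-filling
is equivalent to a morphological binary closing (dilation followed by
erosion) but it never extends a stage past the record ends.  Later stages
in the order operate on the already-modified sequence, so e.g. a 1-epoch
Stage-2 run interrupting REM can be consumed by the REM pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Cohort, Hypnogram, map_stage_codes
from .stages import CANONICAL_STAGES, STAGE_INDEX, decode_stages, encode_stages

#: Default smoothing order: ultradian-cycle stages, most specific first.
DEFAULT_SMOOTH_ORDER: tuple[str, ...] = ("REM", "SWS", "S2")


@dataclass
class Bout:
    """A maximal run of one stage — the unit of dynamic analysis."""

    stage: str
    start_epoch: int
    n_epochs: int
    duration: float           # minutes
    start_clock: float        # minutes since noon
    time_slept_at_start: float  # minutes since sleep onset

    @property
    def stage_code(self) -> int:
        return STAGE_INDEX[self.stage]


def trim_wake(hyp: Hypnogram) -> Hypnogram:
    """Remove wake before sleep onset; sets ``onset_clock``.

    Trailing wake is retained (the data-point builder excludes it from
    outcomes).  Idempotent.  Raises on an all-wake record.
    """
    if not hyp.canonical:
        raise ValueError("trim_wake requires a canonical hypnogram")
    first_sleep = next((i for i, s in enumerate(hyp.stages) if s != "WASO"), None)
    if first_sleep is None:
        raise ValueError("no sleep onset")
    onset = (hyp.onset_clock if hyp.onset_clock is not None else hyp.lights_off_clock)
    onset += first_sleep * hyp.epoch_minutes
    return hyp.replace(stages=hyp.stages[first_sleep:], onset_clock=onset)


def close_gaps(codes: np.ndarray, stage_code: int, max_gap_epochs: int) -> np.ndarray:
    """Fill interior gaps of ``<= max_gap_epochs`` epochs between two runs of
    ``stage_code`` with that stage.

    A gap is a maximal run of non-target epochs lying strictly between two
    target-stage runs; gaps touching either record end are never filled.
    Accepts a 1-D sequence or a 2-D batch (rows = sequences); vectorised so
    that simulation-scale batches are cheap.  Idempotent.
    """
    arr = np.asarray(codes)
    flat = arr.ndim == 1
    a = np.atleast_2d(arr)
    n = a.shape[1]
    target = a == stage_code
    idx = np.arange(n)
    # nearest target index at-or-before / at-or-after each position
    left = np.maximum.accumulate(np.where(target, idx, -1), axis=1)
    right = np.minimum.accumulate(np.where(target, idx, n)[:, ::-1], axis=1)[:, ::-1]
    gap_len = right - left - 1
    fill = (~target) & (left >= 0) & (right < n) & (gap_len <= max_gap_epochs)
    out = a.copy()
    out[fill] = stage_code
    return out[0] if flat else out


def smooth_hypnogram(hyp: Hypnogram, max_gap: float = 1.0,
                     order: tuple[str, ...] = DEFAULT_SMOOTH_ORDER) -> Hypnogram:
    """Ordered gap-closing smoothing (``max_gap`` in minutes, default 1)."""
    if max_gap < 0:
        raise ValueError("invalid gap")
    if not hyp.canonical:
        raise ValueError("smooth_hypnogram requires a canonical hypnogram")
    max_epochs = int(np.floor(max_gap / hyp.epoch_minutes + 1e-9))
    codes = encode_stages(hyp.stages)
    for stage in order:
        codes = close_gaps(codes, STAGE_INDEX[stage], max_epochs)
    return hyp.replace(stages=decode_stages(codes))


def extract_bouts(hyp: Hypnogram) -> list[Bout]:
    """Run-length encode a (canonical, trimmed, optionally smoothed)
    hypnogram into maximal-run bouts.  Total bout duration equals record
    duration."""
    if not hyp.stages:
        raise ValueError("empty record")
    codes = encode_stages(hyp.stages)
    # run boundaries
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(codes)]))
    onset = hyp.onset_clock if hyp.onset_clock is not None else hyp.lights_off_clock
    em = hyp.epoch_minutes
    return [
        Bout(
            stage=CANONICAL_STAGES[codes[s]],
            start_epoch=int(s),
            n_epochs=int(e - s),
            duration=float((e - s) * em),
            start_clock=float(onset + s * em),
            time_slept_at_start=float(s * em),
        )
        for s, e in zip(starts, ends)
    ]


def preprocess_hypnogram(hyp: Hypnogram, smooth: bool = True,
                         max_gap: float = 1.0,
                         order: tuple[str, ...] = DEFAULT_SMOOTH_ORDER
                         ) -> tuple[Hypnogram, list[Bout]]:
    """Canonical pipeline: map codes -> trim pre-onset wake -> smooth ->
    extract bouts.  Returns the processed hypnogram and its bouts."""
    h = map_stage_codes(hyp)
    h = trim_wake(h)
    if smooth:
        h = smooth_hypnogram(h, max_gap=max_gap, order=order)
    return h, extract_bouts(h)


# ---------------------------------------------------------------------------
# Exclusion screening


@dataclass
class ExclusionCriteria:
    """Subject-level screening thresholds.  Defaults are the screening rules
    for a healthy adult cohort: no more-than-mild sleep-disordered
    breathing, ages 18-90, BMI 18.5-50, usual bedtimes, and a plausible
    total sleep time."""

    ahi_max: float = 15.0
    oahi_max: float = 15.0
    oai_max: float = 5.0
    cai_max: float = 5.0
    rdi_max: float = 15.0
    age_min: float = 18.0
    age_max: float = 90.0
    bmi_min: float = 18.5
    bmi_max: float = 50.0
    # minutes since noon: 18:14 -> 374, 01:20 -> 800
    sleep_start_min: float = 374.0
    sleep_start_max: float = 800.0
    tst_min: float = 285.0
    tst_max: float = 650.0
    first_night_only: bool = True
    exclude_disorders: bool = True
    exclude_medicated: bool = True


@dataclass
class ExclusionReport:
    n_input: int = 0
    n_excluded: int = 0
    n_surviving: int = 0
    per_criterion: dict[str, int] = field(default_factory=dict)
    bmi_missing: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "n_surviving": self.n_surviving,
            "per_criterion": dict(self.per_criterion),
            "n_bmi_missing": len(self.bmi_missing),
        }


def _failed_criteria(rec, tst: float | None, onset_clock: float | None,
                     c: ExclusionCriteria) -> list[str]:
    fails = []
    for name, limit in (("ahi", c.ahi_max), ("oahi", c.oahi_max),
                        ("oai", c.oai_max), ("cai", c.cai_max),
                        ("rdi", c.rdi_max)):
        v = getattr(rec, name)
        if v is not None and v > limit:
            fails.append(name)
    if rec.age < c.age_min or rec.age > c.age_max:
        fails.append("age")
    if rec.bmi is not None and not (c.bmi_min <= rec.bmi <= c.bmi_max):
        fails.append("bmi")
    if c.exclude_disorders and rec.disorder_flag:
        fails.append("disorder")
    if c.exclude_medicated and rec.medication_flag:
        fails.append("medication")
    if onset_clock is not None and not (c.sleep_start_min <= onset_clock <= c.sleep_start_max):
        fails.append("sleep_start")
    if tst is not None and not (c.tst_min <= tst <= c.tst_max):
        fails.append("tst")
    return fails


def apply_exclusion_filters(cohort: Cohort,
                            criteria: ExclusionCriteria | None = None
                            ) -> tuple[Cohort, ExclusionReport]:
    """Screen a cohort; returns the surviving cohort and a report.

    Total sleep time and sleep-onset clock are computed on the mapped,
    trimmed record.  A subject with missing BMI is kept but flagged in the
    report (BMI-conditioned models drop those subjects themselves).  An
    empty surviving cohort is a valid outcome.
    """
    c = criteria or ExclusionCriteria()
    report = ExclusionReport(n_input=len(cohort.subjects))
    surviving = Cohort()
    for sid, rec in cohort.subjects.items():
        nights = sorted(k[1] for k in cohort.hypnograms if k[0] == sid)
        if not nights:
            continue
        keep_nights = nights[:1] if c.first_night_only else nights
        hyp = cohort.hypnograms[(sid, keep_nights[0])]
        tst = onset = None
        fails: list[str] = []
        try:
            trimmed = trim_wake(map_stage_codes(hyp))
            tst = sum(1 for s in trimmed.stages if s != "WASO") * trimmed.epoch_minutes
            onset = trimmed.onset_clock
        except ValueError:
            fails.append("no_sleep_onset")
        fails += _failed_criteria(rec, tst, onset, c)
        if fails:
            report.n_excluded += 1
            for f in fails:
                report.per_criterion[f] = report.per_criterion.get(f, 0) + 1
            continue
        if rec.bmi is None:
            report.bmi_missing.append(sid)
        surviving.subjects[sid] = rec
        for night in keep_nights:
            surviving.hypnograms[(sid, night)] = cohort.hypnograms[(sid, night)]
    report.n_surviving = len(surviving.subjects)
    return surviving, report
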