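"""Synthetic hypnogram cohorts with known ground truth.

Each subject's night is generated by a semi-Markov process over the five
canonical stages: bout-to-bout stage transitions follow a first- (or
second-) order chain with zero diagonal, and each bout's duration is drawn
log-normal per stage (stage durations in real hypnograms closely resemble
log-normals), quantised to 30-s epochs with a 1-epoch minimum.  Transition
matrices may vary by time-of-night third, age group and sex; duration
medians may be modulated multiplicatively by the same factors.  The default
chain is the published whole-night first-order transition matrix
(:data:`TABLE1_MATRIX`).

A night starts with a log-normal stretch of pre-onset wake, then bouts from
a configurable onset-stage distribution, and ends with a terminal wake
bout once the configured night length is reached (the last sleep bout is
truncated at the boundary).  Everything is reproducible from the config
seed, and the realised generating parameters are returned as
:class:`GroundTruth` for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io import Cohort, Hypnogram, SubjectRecord
from .stages import STAGE_INDEX, decode_stages

N_STAGES = 5
N_TIME_BINS = 3
N_AGE_GROUPS = 3
N_SEXES = 2

#: Published whole-night first-order bout transition probabilities
#: (rows = from stage, columns = to stage, order WASO,S1,S2,SWS,REM; the
#: impossible diagonal is 0).  The WASO row prints to 0.99 from rounding;
#: rows are renormalised at sampling time only.
TABLE1_MATRIX = np.array([
    # WASO   S1    S2    SWS   REM
    [0.00, 0.64, 0.33, 0.00, 0.02],   # from WASO
    [0.43, 0.00, 0.52, 0.00, 0.05],   # from S1
    [0.44, 0.04, 0.00, 0.31, 0.21],   # from S2
    [0.15, 0.00, 0.80, 0.00, 0.05],   # from SWS
    [0.60, 0.09, 0.31, 0.00, 0.00],   # from REM
])

#: Stage-onset distribution: sleep begins overwhelmingly in light NREM.
DEFAULT_ONSET_PROBS = np.array([0.0, 0.60, 0.35, 0.02, 0.03])

#: Per-stage log-normal bout-duration medians (minutes) and log-SDs; REM
#: bouts run longer than SWS, WASO/S1 interruptions are short.
DEFAULT_DURATION_MEDIAN = np.array([1.5, 1.0, 6.0, 8.0, 10.0])
DEFAULT_DURATION_LOG_SD = np.array([0.8, 0.7, 0.8, 0.8, 0.9])

PLANTED_EFFECTS = (
    "time_on_transitions", "time_on_durations", "age_on_durations",
    "sex_on_transitions", "age_sex_interaction",
)


def _tile_matrices(base: np.ndarray, order: int) -> np.ndarray:
    """Replicate a base chain over (time bin, age group, sex)."""
    shape = (N_TIME_BINS, N_AGE_GROUPS, N_SEXES) + base.shape
    return np.broadcast_to(base, shape).copy()


def second_order_from_first(t1: np.ndarray, carryover: float = 0.3) -> np.ndarray:
    """A second-order chain P(next | prev, current) derived from a
    first-order one: mixture of the current row with the previous row
    (weight ``carryover``), diagonal re-zeroed and renormalised.  Gives a
    genuine dependence on the stage two back for recovery tests."""
    t2 = np.empty((N_STAGES, N_STAGES, N_STAGES))
    for prev in range(N_STAGES):
        for cur in range(N_STAGES):
            row = (1 - carryover) * t1[cur] + carryover * t1[prev]
            row = row.copy()
            row[cur] = 0.0
            t2[prev, cur] = row / row.sum()
    return t2


@dataclass
class SimConfig:
    """Generative parameters of a synthetic cohort.

    ``transition_matrices`` has shape (3 time bins, 3 age groups, 2 sexes,
    5, 5) for ``order=1`` or (..., 5, 5, 5) for ``order=2``; defaults
    replicate :data:`TABLE1_MATRIX` across every stratum (no planted
    effects).  Duration multipliers are per (stratum, stage).
    """

    n_subjects: int = 200
    n_datasets: int = 3
    order: int = 1
    age_range: tuple[float, float] = (18.0, 90.0)
    sex_p_male: float = 0.5
    bmi_median: float = 24.0
    bmi_log_sd: float = 0.15
    transition_matrices: np.ndarray | None = None
    onset_probs: np.ndarray = field(default_factory=lambda: DEFAULT_ONSET_PROBS.copy())
    duration_median: np.ndarray = field(default_factory=lambda: DEFAULT_DURATION_MEDIAN.copy())
    duration_log_sd: np.ndarray = field(default_factory=lambda: DEFAULT_DURATION_LOG_SD.copy())
    duration_time_mult: np.ndarray = field(default_factory=lambda: np.ones((N_TIME_BINS, N_STAGES)))
    duration_age_mult: np.ndarray = field(default_factory=lambda: np.ones((N_AGE_GROUPS, N_STAGES)))
    duration_sex_mult: np.ndarray = field(default_factory=lambda: np.ones((N_SEXES, N_STAGES)))
    wake_before_onset_median: float = 10.0  # minutes
    wake_before_onset_log_sd: float = 0.6
    lights_off_mean: float = 690.0   # 23:30, minutes since noon
    lights_off_sd: float = 40.0
    night_length_range: tuple[float, float] = (360.0, 480.0)  # minutes
    terminal_wake_minutes: float = 5.0
    epoch_seconds: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if self.transition_matrices is None:
            base = (TABLE1_MATRIX if self.order == 1
                    else second_order_from_first(TABLE1_MATRIX / TABLE1_MATRIX.sum(1, keepdims=True)))
            self.transition_matrices = _tile_matrices(base, self.order)
        self._validate()

    def _validate(self):
        m = np.asarray(self.transition_matrices, float)
        want_tail = (N_STAGES,) * (self.order + 1)
        if m.shape != (N_TIME_BINS, N_AGE_GROUPS, N_SEXES) + want_tail:
            raise ValueError("invalid transition matrix shape")
        diag = np.einsum("...ii->...i", m.reshape(-1, N_STAGES, N_STAGES))
        if np.any(diag != 0):
            raise ValueError("invalid transition matrix: nonzero diagonal")
        sums = m.sum(axis=-1)
        if np.any(sums <= 0) or np.any(np.abs(sums - 1.0) > 0.02):
            raise ValueError("invalid transition matrix: rows not stochastic")
        if np.any(np.asarray(self.duration_median) <= 0):
            raise ValueError("duration medians must be positive")
        if self.night_length_range[0] <= 0:
            raise ValueError("invalid config: zero night length")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def normalized_matrices(self) -> np.ndarray:
        m = np.asarray(self.transition_matrices, float)
        return m / m.sum(axis=-1, keepdims=True)


@dataclass
class GroundTruth:
    """Realised generating parameters of a simulated cohort."""

    transition_matrices: np.ndarray  # row-normalised, per stratum
    onset_probs: np.ndarray
    duration_median: np.ndarray
    duration_log_sd: np.ndarray
    duration_time_mult: np.ndarray
    duration_age_mult: np.ndarray
    duration_sex_mult: np.ndarray
    order: int

    def duration_median_for(self, time_bin: int, age_group: int, sex: int) -> np.ndarray:
        return (self.duration_median * self.duration_time_mult[time_bin]
                * self.duration_age_mult[age_group] * self.duration_sex_mult[sex])


def table1_config(**overrides) -> SimConfig:
    """A first-order, time-homogeneous config whose chain is the printed
    whole-night matrix (diagonal 0).  Row sums within 0.01 of 1 are kept as
    printed; normalisation happens only inside the sampler."""
    return SimConfig(order=1, **overrides)


def planted_effect_config(base: SimConfig, effect: str,
                          magnitude: float = 0.5) -> SimConfig:
    """Apply a named modulation to a config, at a stated magnitude.

    ``magnitude`` m scales each effect: e.g. ``age_on_durations`` sets the
    older group's duration multiplier to (1 - m) and the younger group's to
    (1 + m/2) for the sleep-maintenance stages; ``time_on_transitions``
    scales P(-> SWS) by (1 - m) in the last time bin (renormalised).
    """
    if effect is None or effect == "none":
        return base
    if effect not in PLANTED_EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    m = float(magnitude)
    if not 0 <= m < 1:
        raise ValueError("magnitude must be in [0, 1)")
    cfg = base
    sws = STAGE_INDEX["SWS"]
    waso = STAGE_INDEX["WASO"]

    def renorm(mats: np.ndarray) -> np.ndarray:
        return mats / mats.sum(axis=-1, keepdims=True)

    if effect == "time_on_transitions":
        mats = cfg.transition_matrices.copy()
        mats[-1, ..., sws] *= (1 - m)
        cfg = cfg.replace(transition_matrices=renorm(mats))
    elif effect == "time_on_durations":
        mult = cfg.duration_time_mult.copy()
        mult[0, :] *= (1 + m / 2)
        mult[-1, :] *= (1 - m / 2)
        cfg = cfg.replace(duration_time_mult=mult)
    elif effect == "age_on_durations":
        # fragmentation begins at mid age and is strongest in later life;
        # older adults' awakenings, by contrast, run longer
        mult = cfg.duration_age_mult.copy()
        mult[0, :] *= (1 + m / 2)       # younger: longer bouts
        mult[1, :] *= (1 - 0.6 * m)     # mid age: shorter
        mult[2, :] *= (1 - m)           # older: shortest
        mult[2, waso] *= (1 + 2 * m) / (1 - m)
        cfg = cfg.replace(duration_age_mult=mult)
    elif effect == "sex_on_transitions":
        mats = cfg.transition_matrices.copy()
        mats[:, :, 1, ..., sws] *= (1 - m)   # males transition to SWS less
        mats[:, :, 1, ..., waso] *= (1 + m)
        cfg = cfg.replace(transition_matrices=renorm(mats))
    elif effect == "age_sex_interaction":
        # deeper-NREM transitions drop from mid age on, more so for males;
        # wake/S1 transitions rise in step, strongest for older males
        mats = cfg.transition_matrices.copy()
        s1, s2 = STAGE_INDEX["S1"], STAGE_INDEX["S2"]
        for g, age_w in ((1, 0.5), (2, 1.0)):
            for s, sex_w in ((0, 0.8), (1, 1.2)):
                r = min(m * age_w * sex_w, 0.95)
                mats[:, g, s, ..., sws] *= (1 - r)
                mats[:, g, s, ..., s2] *= (1 - 0.6 * r)
                mats[:, g, s, ..., waso] *= (1 + r)
                mats[:, g, s, ..., s1] *= (1 + 0.5 * r)
        cfg = cfg.replace(transition_matrices=renorm(mats))
    return cfg


def _age_group(age: float) -> int:
    return int(np.searchsorted([43.0, 67.0], age, side="right"))


def simulate_subject(rng: np.random.Generator, cfg: SimConfig,
                     age: float, sex: int, matrices: np.ndarray
                     ) -> tuple[np.ndarray, float, float]:
    """One night: returns (epoch stage codes, lights-off clock, night
    length in minutes).  ``matrices`` are the row-normalised chains for
    this subject's strata, indexed by time bin."""
    em = cfg.epoch_seconds / 60.0
    night_len = rng.uniform(*cfg.night_length_range)
    lights_off = float(np.clip(rng.normal(cfg.lights_off_mean, cfg.lights_off_sd),
                               380.0, 795.0))
    pre_wake = rng.lognormal(np.log(cfg.wake_before_onset_median),
                             cfg.wake_before_onset_log_sd)
    pre_epochs = max(1, int(round(pre_wake / em)))
    ag = _age_group(age)
    onset = cfg.onset_probs / cfg.onset_probs.sum()
    med_base = cfg.duration_median * cfg.duration_age_mult[ag] * cfg.duration_sex_mult[sex]
    epochs: list[int] = [STAGE_INDEX["WASO"]] * pre_epochs
    slept = 0.0
    prev = -1
    cur = int(rng.choice(N_STAGES, p=onset))
    max_epochs_night = int(round(night_len / em))
    n_sleep_epochs = 0
    while n_sleep_epochs < max_epochs_night:
        tb = min(int(slept / night_len * N_TIME_BINS), N_TIME_BINS - 1)
        med = med_base[cur] * cfg.duration_time_mult[tb, cur]
        dur = rng.lognormal(np.log(med), cfg.duration_log_sd[cur])
        n_ep = max(1, int(round(dur / em)))
        n_ep = min(n_ep, max_epochs_night - n_sleep_epochs)  # truncate at night end
        epochs.extend([cur] * n_ep)
        n_sleep_epochs += n_ep
        slept += n_ep * em
        if cfg.order == 2:
            # no previous bout yet: average the second-order rows over it
            row = (matrices[tb, prev, cur] if prev >= 0
                   else matrices[tb, :, cur].mean(axis=0))
        else:
            row = matrices[tb, cur]
        nxt = int(rng.choice(N_STAGES, p=row / row.sum()))
        prev, cur = cur, nxt
    term_epochs = max(1, int(round(cfg.terminal_wake_minutes / em)))
    epochs.extend([STAGE_INDEX["WASO"]] * term_epochs)
    return np.asarray(epochs, dtype=np.int8), lights_off, night_len


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort of hypnograms plus metadata; byte-reproducible
    given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    norm = cfg.normalized_matrices()
    cohort = Cohort()
    for i in range(cfg.n_subjects):
        sid = f"s{i:05d}"
        ds = f"d{i % cfg.n_datasets}"
        age = float(rng.uniform(*cfg.age_range))
        sex = int(rng.random() < cfg.sex_p_male)
        bmi = float(rng.lognormal(np.log(cfg.bmi_median), cfg.bmi_log_sd))
        ag = _age_group(age)
        mats = norm[:, ag, sex]  # (time bins, ...)
        codes, lights_off, _night = simulate_subject(rng, cfg, age, sex, mats)
        rec = SubjectRecord(subject_id=sid, dataset_id=ds, age=age,
                            sex="M" if sex else "F", bmi=bmi,
                            lights_off_clock=lights_off,
                            ahi=0.0, oahi=0.0, oai=0.0, cai=0.0, rdi=0.0)
        hyp = Hypnogram(subject_id=sid, dataset_id=ds,
                        stages=decode_stages(codes),
                        epoch_seconds=cfg.epoch_seconds,
                        lights_off_clock=lights_off, canonical=True)
        cohort.add(hyp, rec)
    truth = GroundTruth(
        transition_matrices=norm,
        onset_probs=cfg.onset_probs / cfg.onset_probs.sum(),
        duration_median=cfg.duration_median.copy(),
        duration_log_sd=cfg.duration_log_sd.copy(),
        duration_time_mult=cfg.duration_time_mult.copy(),
        duration_age_mult=cfg.duration_age_mult.copy(),
        duration_sex_mult=cfg.duration_sex_mult.copy(),
        order=cfg.order,
    )
    return cohort, truth


def simulate_stage_sequence(n_transitions: int, seed: int = 0,
                            matrix: np.ndarray | None = None) -> np.ndarray:
    """A bare bout-stage chain (no durations): ``n_transitions``+1 stage
    codes from the (normalised) first-order matrix, starting from WASO's
    successor distribution.  Handy for transition-recovery checks."""
    m = TABLE1_MATRIX if matrix is None else np.asarray(matrix, float)
    m = m / m.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(m, axis=1)
    out = np.empty(n_transitions + 1, dtype=np.int8)
    out[0] = STAGE_INDEX["S1"]
    u = rng.random(n_transitions)
    for i in range(n_transitions):
        out[i + 1] = np.searchsorted(cdf[out[i]], u[i], side="right")
    return out
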