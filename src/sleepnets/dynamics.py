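"""Transition-probability and duration-distribution analytics.

Transition probabilities of order k are estimated by counting transitions
(to stage i, or to stage i from stage j, ...) and normalising by the total
number of transitions in the conditioned subset.  Rows with no conditioning
counts are reported as undefined (NaN), never silently uniform.  The
first-order diagonal is identically zero: bouts are maximal runs, so a
stage never "transitions" to itself.

Expected stage durations convert the 4-bin duration distribution back to
minutes by a dot product with the stage's bin midpoints.  Generalisability
across sources is probed by leave-one-dataset-out refits, and uncertainty
by a subject-level (cluster) bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bayesnet import DiscreteBayesianNetwork, fit_parameters, k2_search
from .datapoints import DiscretizationScheme, _bin_durations, complete_cases
from .models import node_order
from .preprocess import Bout
from .stages import CANONICAL_STAGES, STAGE_INDEX

N_STAGES = len(CANONICAL_STAGES)


@dataclass
class TransitionMatrix:
    """P(stage_t | history) of order 0, 1 or 2 with raw counts.

    ``probs`` has shape (5,), (5, 5) or (5, 5, 5); the trailing axis is the
    destination stage.  Undefined rows (zero count) are NaN."""

    order: int
    probs: np.ndarray
    counts: np.ndarray
    condition: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        flat = self.probs.reshape(-1, N_STAGES)
        if self.order == 0:
            index = ["any"]
        elif self.order == 1:
            index = list(CANONICAL_STAGES)
        else:
            index = [f"{a}<-{b}" for a in CANONICAL_STAGES for b in CANONICAL_STAGES]
            flat = self.probs.transpose(1, 0, 2).reshape(-1, N_STAGES)
        return pd.DataFrame(flat, index=index, columns=CANONICAL_STAGES)


@dataclass
class DurationDistribution:
    stage: str
    probs: np.ndarray       # 4 bin probabilities
    midpoints: np.ndarray   # minutes


def _transitions_from_bouts(records: Sequence[Sequence[Bout]]
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(stage_t2, stage_t1, stage_t) code triples over all records,
    excluding any transition into a terminal wake bout (lag codes are -1
    when the history does not exist)."""
    t2, t1, t0 = [], [], []
    for bouts in records:
        n = len(bouts)
        for i in range(1, n):
            if i == n - 1 and bouts[i].stage == "WASO":
                continue
            t0.append(bouts[i].stage_code)
            t1.append(bouts[i - 1].stage_code)
            t2.append(bouts[i - 2].stage_code if i >= 2 else -1)
    return (np.asarray(t2, int), np.asarray(t1, int), np.asarray(t0, int))


def transition_probabilities(data, order: int = 1,
                             condition: dict[str, int] | None = None
                             ) -> TransitionMatrix:
    """Count-and-normalise transition probabilities.

    ``data`` is either a discrete data-point table (with ``stage_t`` and
    the lag columns it needs) or a sequence of per-record bout lists.
    ``condition`` restricts a data-point table to an assignment of
    time/demographic bins before counting.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    if isinstance(data, pd.DataFrame):
        df = data
        if condition:
            for var, val in condition.items():
                if var not in df.columns:
                    raise ValueError(f"no column {var!r} to condition on")
                df = df[df[var] == val]
        needed = ["stage_t", "stage_t1", "stage_t2"][: order + 1]
        df = complete_cases(df, needed)
        cols = [df[c].to_numpy() for c in needed]
    else:
        if condition:
            raise ValueError("conditioning requires a data-point table")
        t2, t1, t0 = _transitions_from_bouts(data)
        cols = [t0, t1, t2][: order + 1]
        keep = np.ones(len(t0), bool)
        for c in cols:
            keep &= c >= 0
        cols = [c[keep] for c in cols]
    n = len(cols[0])
    if n == 0:
        raise ValueError("no transitions under condition")
    dims = (N_STAGES,) * (order + 1)
    # cols are (stage_t, stage_t1, stage_t2); index counts as [t1..][t]
    idx = list(reversed(cols[1:])) + [cols[0]]
    flat = np.ravel_multi_index(idx, dims) if order else cols[0]
    counts = np.bincount(flat, minlength=N_STAGES ** (order + 1)).reshape(dims)
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
    return TransitionMatrix(order=order, probs=probs, counts=counts,
                            condition=dict(condition or {}))


def duration_distribution(points: pd.DataFrame, stage: str,
                          scheme: DiscretizationScheme,
                          condition: dict[str, int] | None = None
                          ) -> DurationDistribution:
    """Normalised 4-bin histogram of a stage's current-bout durations."""
    df = points
    if condition:
        for var, val in condition.items():
            df = df[df[var] == val]
    durs = df.loc[df["stage_t"] == stage, "dur_t"].to_numpy(float)
    durs = durs[~np.isnan(durs)]
    if len(durs) == 0:
        raise ValueError(f"no data for stage {stage}")
    code = STAGE_INDEX[stage]
    bins = _bin_durations(durs, np.full(len(durs), code), scheme)
    counts = np.bincount(bins, minlength=4)
    return DurationDistribution(stage=stage, probs=counts / counts.sum(),
                                midpoints=scheme.duration_midpoints[stage])


def expected_duration(dist: DurationDistribution) -> float:
    """Dot product of the bin probabilities with the bin midpoints."""
    return float(np.dot(dist.probs, dist.midpoints))


@dataclass
class ConditionalParameters:
    condition: dict[str, int]
    transition: np.ndarray               # P(stage_t | condition), 0th order
    expected_durations: dict[str, float]  # minutes per stage
    duration_probs: dict[str, np.ndarray]


def conditional_parameters(network: DiscreteBayesianNetwork,
                           condition: dict[str, int],
                           scheme: DiscretizationScheme
                           ) -> ConditionalParameters:
    """Model-implied 0th-order transition probabilities and expected
    durations under a time/demographic assignment (e.g. start of night =
    Time of Day bin 0, Time Slept bin 0)."""
    for var in condition:
        if var not in network.structure.cards:
            raise ValueError(f"{var!r} not conditioned in model")
    p_stage = network.posterior("stage_t", condition)
    exp_d, dur_p = {}, {}
    for stage in CANONICAL_STAGES:
        ev = dict(condition)
        ev["stage_t"] = STAGE_INDEX[stage]
        p = network.posterior("dur_t", ev)
        dur_p[stage] = p
        exp_d[stage] = float(np.dot(p, scheme.duration_midpoints[stage]))
    return ConditionalParameters(condition=dict(condition),
                                 transition=p_stage,
                                 expected_durations=exp_d,
                                 duration_probs=dur_p)


#: Start / middle / end of night as diagonal (Time of Day, Time Slept) bins.
NIGHT_PHASES: dict[str, dict[str, int]] = {
    "start": {"time_of_day": 0, "time_slept": 0},
    "middle": {"time_of_day": 1, "time_slept": 1},
    "end": {"time_of_day": 2, "time_slept": 2},
}


@dataclass
class ParameterSpread:
    """One statistic refit with each source dataset left out in turn."""

    label: str
    values: pd.Series  # indexed by left-out dataset id

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


def loo_dataset_parameters(discrete_points: pd.DataFrame,
                           variables: list[str],
                           statistic: Callable[[DiscreteBayesianNetwork], dict[str, float]],
                           pseudo_count: float = 1.0,
                           max_parents: int | None = None
                           ) -> dict[str, ParameterSpread]:
    """Refit the model once per left-out dataset and collect a statistic.

    ``statistic`` maps a fitted network to named scalar parameters; the
    returned spreads carry the per-left-out values plus mean and SD.
    """
    datasets = sorted(discrete_points["dataset_id"].unique())
    if len(datasets) < 2:
        raise ValueError("need >=2 datasets")
    order = node_order(variables)
    rows: dict[str, dict[str, float]] = {}
    for left_out in datasets:
        sub = discrete_points[discrete_points["dataset_id"] != left_out]
        sub = complete_cases(sub, variables)
        structure = k2_search(sub, order, max_parents=max_parents)
        net = fit_parameters(structure, sub, pseudo_count=pseudo_count)
        for label, value in statistic(net).items():
            rows.setdefault(label, {})[left_out] = value
    return {label: ParameterSpread(label, pd.Series(vals))
            for label, vals in rows.items()}


def bootstrap_ci(points: pd.DataFrame,
                 statistic: Callable[[pd.DataFrame], float],
                 B: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval, resampling subjects (clusters) with
    replacement — data points within a subject are not independent.
    Resamples on which the statistic is undefined (raises or returns NaN)
    are redrawn."""
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    pts = points.reset_index(drop=True)
    codes, subjects = pd.factorize(pts["subject_id"])
    rows_of = [np.flatnonzero(codes == i) for i in range(len(subjects))]
    stats = np.empty(B)
    redraws = 0
    for b in range(B):
        for _attempt in range(100):
            draw = rng.integers(0, len(subjects), size=len(subjects))
            idx = np.concatenate([rows_of[i] for i in draw])
            try:
                v = statistic(pts.iloc[idx])
            except (ValueError, ZeroDivisionError):
                v = np.nan
            if np.isfinite(v):
                stats[b] = v
                break
            redraws += 1
        else:
            raise ValueError("statistic undefined on every resample")
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    interval = (float(np.quantile(stats, lo)), float(np.quantile(stats, hi)))
    bootstrap_ci.last_redraws = redraws  # logged for inspection
    return interval
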