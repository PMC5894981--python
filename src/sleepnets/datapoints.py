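"""From bout sequences to model-ready data points, and their discretization.

One data point per bout: the bout's stage and duration at *t*, the stage
identity/duration of up to three preceding bouts (t-1..t-3), the bout's
start clock time (Time of Day), time since sleep onset (Time Slept), and
the subject's demographics.  A terminal wake bout is never an outcome:
transitions into final wake are not sleep dynamics.

Continuous fields are discretized for the network models:

* per-stage bout durations into 4 logarithmically spaced bins from the
  stage's minimum duration to its 95th percentile, the last bin open above
  (the top 5% falls into bin 4);
* Time of Day and Time Slept into empirical tertiles;
* age into fixed tripartition 18-42 / 43-66 / 67-90;
* BMI split at 25 kg/m².

The fitted scheme is held by :class:`HypnogramDiscretizer`, a scikit-learn
transformer, so it can sit in a Pipeline and be reused bit-exactly across
runs (``scheme_`` serialises to plain dicts).

All discrete codes are 0-based; a missing value (absent history, missing
BMI) is the sentinel ``-1`` and models drop such rows for the variables
they condition on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SubjectRecord
from .preprocess import Bout
from .stages import CANONICAL_STAGES, STAGE_INDEX

MAX_HISTORY = 3

STAGE_VARS = ["stage_t", "stage_t1", "stage_t2", "stage_t3"]
DUR_VARS = ["dur_t", "dur_t1", "dur_t2", "dur_t3"]

#: Cardinalities and ordered category labels of every model variable.
VARIABLE_LABELS: dict[str, list[str]] = {
    **{v: list(CANONICAL_STAGES) for v in STAGE_VARS},
    **{v: ["bin1", "bin2", "bin3", "bin4"] for v in DUR_VARS},
    "time_of_day": ["early", "mid", "late"],
    "time_slept": ["early", "mid", "late"],
    "age": ["younger", "mid", "older"],
    "sex": ["F", "M"],
    "bmi": ["low", "high"],
}

VARIABLE_CARDS: dict[str, int] = {k: len(v) for k, v in VARIABLE_LABELS.items()}

#: Pairs of stage variables at adjacent lags; bouts are maximal runs, so
#: the two members of each pair can never be equal (structural zeros).
ADJACENT_STAGE_PAIRS: list[tuple[str, str]] = [
    ("stage_t", "stage_t1"),
    ("stage_t1", "stage_t2"),
    ("stage_t2", "stage_t3"),
]


def build_datapoints(records: list[tuple[list[Bout], SubjectRecord]]) -> pd.DataFrame:
    """Build the continuous data-point table from per-record bout sequences.

    ``records`` pairs each record's bouts (trimmed + smoothed) with its
    subject metadata.  Returns one row per bout, excluding a terminal WASO
    bout, with NaN/None for absent history and missing BMI.
    """
    rows = []
    for bouts, rec in records:
        if rec is None:
            raise ValueError("unknown subject: bout record with no metadata")
        n = len(bouts)
        for i, b in enumerate(bouts):
            if i == n - 1 and b.stage == "WASO":
                continue  # terminal wake is never an outcome
            row = {
                "subject_id": rec.subject_id,
                "dataset_id": rec.dataset_id,
                "stage_t": b.stage,
                "dur_t": b.duration,
                "time_of_day": b.start_clock,
                "time_slept": b.time_slept_at_start,
                "age": rec.age,
                "sex": rec.sex,
                "bmi": rec.bmi if rec.bmi is not None else np.nan,
            }
            for k in range(1, MAX_HISTORY + 1):
                prev = bouts[i - k] if i - k >= 0 else None
                row[f"stage_t{k}"] = prev.stage if prev else None
                row[f"dur_t{k}"] = prev.duration if prev else np.nan
            rows.append(row)
    cols = (["subject_id", "dataset_id", "stage_t", "dur_t",
             "stage_t1", "dur_t1", "stage_t2", "dur_t2", "stage_t3", "dur_t3",
             "time_of_day", "time_slept", "age", "sex", "bmi"])
    return pd.DataFrame(rows, columns=cols)


def cohort_datapoints(cohort, smooth: bool = True, max_gap: float = 1.0,
                      drop_censored_final_bout: bool = False) -> pd.DataFrame:
    """Run the preprocessing pipeline over a whole cohort and build the
    continuous data-point table.

    ``drop_censored_final_bout`` removes each record's last sleep bout,
    which in fixed-length records is right-censored by the record end;
    duration-recovery studies use this to avoid length-biased censoring.
    """
    from .preprocess import preprocess_hypnogram

    records = []
    for hyp in cohort.hypnograms.values():
        _, bouts = preprocess_hypnogram(hyp, smooth=smooth, max_gap=max_gap)
        if drop_censored_final_bout:
            last_sleep = max((i for i, b in enumerate(bouts) if b.stage != "WASO"),
                             default=None)
            if last_sleep is not None:
                bouts = bouts[:last_sleep] + bouts[last_sleep + 1:]
        records.append((bouts, cohort.subjects[hyp.subject_id]))
    return build_datapoints(records)


def _quantile(x: np.ndarray, q: float) -> float:
    # nearest-rank (type 1) for determinism across implementations
    return float(np.quantile(x, q, method="inverted_cdf"))


@dataclass
class DiscretizationScheme:
    """Frozen bin edges (and duration-bin midpoints) for every variable."""

    duration_edges: dict[str, np.ndarray]      # stage -> 5 increasing edges
    duration_midpoints: dict[str, np.ndarray]  # stage -> 4 geometric midpoints
    tod_edges: tuple[float, float]
    ts_edges: tuple[float, float]
    age_edges: tuple[float, float] = (43.0, 67.0)
    bmi_split: float = 25.0

    def to_dict(self) -> dict:
        return {
            "duration_edges": {s: list(map(float, e)) for s, e in self.duration_edges.items()},
            "duration_midpoints": {s: list(map(float, m)) for s, m in self.duration_midpoints.items()},
            "tod_edges": list(self.tod_edges),
            "ts_edges": list(self.ts_edges),
            "age_edges": list(self.age_edges),
            "bmi_split": self.bmi_split,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationScheme":
        return cls(
            duration_edges={s: np.asarray(e, float) for s, e in d["duration_edges"].items()},
            duration_midpoints={s: np.asarray(m, float) for s, m in d["duration_midpoints"].items()},
            tod_edges=tuple(d["tod_edges"]),
            ts_edges=tuple(d["ts_edges"]),
            age_edges=tuple(d["age_edges"]),
            bmi_split=float(d["bmi_split"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def log_spaced_edges(lo: float, hi: float, n_bins: int = 4) -> np.ndarray:
    """n_bins+1 logarithmically spaced edges from lo to hi (a geometric
    progression with ratio (hi/lo)**(1/n_bins))."""
    if not (0 < lo < hi):
        raise ValueError("edges require 0 < lo < hi")
    return lo * (hi / lo) ** (np.arange(n_bins + 1) / n_bins)


def fit_discretization(points: pd.DataFrame, min_per_stage: int = 20,
                       age_edges: tuple[float, float] = (43.0, 67.0),
                       bmi_split: float = 25.0) -> DiscretizationScheme:
    """Fit the scheme on a continuous data-point table.

    Duration edges come from the current-bout (stage_t, dur_t) pairs of
    each stage: 5 log-spaced values from the minimum to the 95th percentile
    (nearest-rank), the 4th bin extended to +inf at binning time.  Bin
    midpoints are the geometric midpoints of consecutive edges.
    """
    duration_edges: dict[str, np.ndarray] = {}
    midpoints: dict[str, np.ndarray] = {}
    for stage in CANONICAL_STAGES:
        durs = points.loc[points["stage_t"] == stage, "dur_t"].to_numpy(float)
        durs = durs[~np.isnan(durs)]
        if len(durs) < min_per_stage:
            raise ValueError(f"insufficient data for stage {stage}")
        lo, hi = float(durs.min()), _quantile(durs, 0.95)
        if not hi > lo:
            raise ValueError(f"degenerate durations for stage {stage}")
        edges = log_spaced_edges(lo, hi)
        duration_edges[stage] = edges
        midpoints[stage] = np.sqrt(edges[:-1] * edges[1:])
    tod = points["time_of_day"].to_numpy(float)
    ts = points["time_slept"].to_numpy(float)
    return DiscretizationScheme(
        duration_edges=duration_edges,
        duration_midpoints=midpoints,
        tod_edges=(_quantile(tod, 1 / 3), _quantile(tod, 2 / 3)),
        ts_edges=(_quantile(ts, 1 / 3), _quantile(ts, 2 / 3)),
        age_edges=age_edges,
        bmi_split=bmi_split,
    )


def _bin_durations(dur: np.ndarray, stage_codes: np.ndarray,
                   scheme: DiscretizationScheme) -> np.ndarray:
    """Stage-specific 4-bin indices; half-open [lo, hi) bins, below-range
    clamps to bin 0, at/above the last interior edge falls in bin 3."""
    out = np.full(len(dur), -1, dtype=np.int8)
    for code, stage in enumerate(CANONICAL_STAGES):
        sel = stage_codes == code
        if not sel.any():
            continue
        interior = scheme.duration_edges[stage][1:4]
        out[sel] = np.searchsorted(interior, dur[sel], side="right")
    out[np.isnan(dur)] = -1
    return out


def discretize(points: pd.DataFrame, scheme: DiscretizationScheme) -> pd.DataFrame:
    """Apply a fitted scheme; every continuous field becomes a 0-based bin
    code, missing values become -1.  Deterministic and total (values beyond
    the fitted range clamp into the outer bins)."""
    out = pd.DataFrame(index=points.index)
    for col in ("subject_id", "dataset_id"):
        if col in points:
            out[col] = points[col]
    for sv in STAGE_VARS:
        labels = points[sv]
        out[sv] = np.array(
            [STAGE_INDEX[s] if isinstance(s, str) else -1 for s in labels],
            dtype=np.int8)
    for sv, dv in zip(STAGE_VARS, DUR_VARS):
        out[dv] = _bin_durations(points[dv].to_numpy(float),
                                 out[sv].to_numpy(), scheme)
    tod = points["time_of_day"].to_numpy(float)
    ts = points["time_slept"].to_numpy(float)
    out["time_of_day"] = np.searchsorted(np.asarray(scheme.tod_edges), tod,
                                         side="right").astype(np.int8)
    out["time_slept"] = np.searchsorted(np.asarray(scheme.ts_edges), ts,
                                        side="right").astype(np.int8)
    age = points["age"].to_numpy(float)
    out["age"] = np.searchsorted(np.asarray(scheme.age_edges), age,
                                 side="right").astype(np.int8)
    out["sex"] = np.array([{"F": 0, "M": 1}.get(s, -1) for s in points["sex"]],
                          dtype=np.int8)
    bmi = points["bmi"].to_numpy(float)
    out["bmi"] = np.where(np.isnan(bmi), -1, (bmi >= scheme.bmi_split)).astype(np.int8)
    return out


def complete_cases(discrete: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Rows with no missing (-1) value in ``variables``; a model
    conditioning on lag k keeps only points with k-deep history."""
    mask = np.ones(len(discrete), dtype=bool)
    for v in variables:
        mask &= discrete[v].to_numpy() >= 0
    return discrete.loc[mask]


class HypnogramDiscretizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the discretization scheme.

    Parameters
    ----------
    min_per_stage : minimum current-bout count per stage needed to fit
        that stage's duration bins.
    age_edges, bmi_split : the fixed demographic cut points.

    Attributes
    ----------
    scheme_ : DiscretizationScheme
        The fitted bin edges and midpoints.
    """

    def __init__(self, min_per_stage: int = 20,
                 age_edges: tuple[float, float] = (43.0, 67.0),
                 bmi_split: float = 25.0):
        self.min_per_stage = min_per_stage
        self.age_edges = age_edges
        self.bmi_split = bmi_split

    def fit(self, X: pd.DataFrame, y=None) -> "HypnogramDiscretizer":
        self.scheme_ = fit_discretization(
            X, min_per_stage=self.min_per_stage,
            age_edges=tuple(self.age_edges), bmi_split=self.bmi_split)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "scheme_"):
            raise ValueError("HypnogramDiscretizer is not fitted")
        return discretize(X, self.scheme_)
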