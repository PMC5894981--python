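"""The nine model families over sleep-architecture variables.

Family 1 varies the depth of previous-stage information alone
(1A = 1 back, 1B = 2 back, 1C = 3 back); family 2 adds Time of Day and
Time Slept (2A = no history, 2B = 1 back, 2C = 2 back); family 3 further
adds Age, Sex and BMI (3A/3B/3C mirror 2A/2B/2C).  Every family contains
the current stage identity and its duration.
"""

from __future__ import annotations

_LAG = {
    0: ["stage_t", "dur_t"],
    1: ["stage_t1", "dur_t1"],
    2: ["stage_t2", "dur_t2"],
    3: ["stage_t3", "dur_t3"],
}
_TIME = ["time_of_day", "time_slept"]
_DEMO = ["age", "sex", "bmi"]


def _lags(k: int) -> list[str]:
    out: list[str] = []
    for i in range(k + 1):
        out += _LAG[i]
    return out


MODEL_FAMILIES: dict[str, list[str]] = {
    "1A": _lags(1),
    "1B": _lags(2),
    "1C": _lags(3),
    "2A": _lags(0) + _TIME,
    "2B": _lags(1) + _TIME,
    "2C": _lags(2) + _TIME,
    "3A": _lags(0) + _TIME + _DEMO,
    "3B": _lags(1) + _TIME + _DEMO,
    "3C": _lags(2) + _TIME + _DEMO,
}

#: K2 node order: demographics, then the two-process time variables, then
#: the past from deepest lag forward, then the present.  Parents may only
#: precede children, matching temporal causality (the past and the person
#: point into the present, never backwards).
FULL_NODE_ORDER: list[str] = [
    "age", "sex", "bmi", "time_of_day", "time_slept",
    "stage_t3", "dur_t3", "stage_t2", "dur_t2", "stage_t1", "dur_t1",
    "stage_t", "dur_t",
]


def model_variables(name: str) -> list[str]:
    try:
        return list(MODEL_FAMILIES[name])
    except KeyError:
        raise ValueError(f"unknown model family {name!r}") from None


def node_order(variables: list[str]) -> list[str]:
    """The K2 ordering restricted to ``variables``."""
    missing = set(variables) - set(FULL_NODE_ORDER)
    if missing:
        raise ValueError(f"unknown variables {sorted(missing)}")
    return [v for v in FULL_NODE_ORDER if v in variables]
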