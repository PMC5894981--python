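import pytest
from hypothesis import settings

import sleepnets as sn

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_subject(sid="s1", dataset="dsA", age=35.0, sex="F", bmi=22.1,
                 lights_off="23:00", **kw):
    return sn.SubjectRecord(
        subject_id=sid, dataset_id=dataset, age=age, sex=sex, bmi=bmi,
        lights_off_clock=sn.stages.parse_clock(lights_off), **kw)


def make_hypnogram(stages, sid="s1", dataset="dsA", lights_off="23:00",
                   canonical=True, **kw):
    return sn.Hypnogram(subject_id=sid, dataset_id=dataset, stages=list(stages),
                        lights_off_clock=sn.stages.parse_clock(lights_off),
                        canonical=canonical, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-subject homogeneous cohort from the default first-order chain."""
    cohort, truth = sn.simulate_cohort(sn.table1_config(n_subjects=80, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def small_points(small_cohort):
    cohort, _ = small_cohort
    return sn.cohort_datapoints(cohort, smooth=False)


@pytest.fixture(scope="session")
def small_discrete(small_points):
    disc = sn.HypnogramDiscretizer().fit(small_points)
    return disc.transform(small_points), disc.scheme_
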