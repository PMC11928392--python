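import dataclasses
import math

import numpy as np
import pytest

from rptdose import CohortConfig, generate_cohort
from rptdose.kinetics import ActivitySample, fit_all

LN2 = math.log(2.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def mono_samples(amp, lam, times, organ="tumor", patient="P1", cycle=1):
    return [
        ActivitySample(patient, cycle, organ, t, amp * math.exp(-lam * t))
        for t in times
    ]


def biexp_samples(a1, l1, a2, l2, times, organ="tumor", patient="P1", cycle=1):
    return [
        ActivitySample(patient, cycle, organ, t,
                       a1 * math.exp(-l1 * t) - a2 * math.exp(-l2 * t))
        for t in times
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort shared by integration tests."""
    cfg = dataclasses.replace(CohortConfig(rng_seed=11), n_patients=8)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    return fit_all(small_cohort.activity)
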