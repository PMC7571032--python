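"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from aarisk import defaults, synthetic


@pytest.fixture(scope="session")
def study_config():
    return synthetic.default_config(seed=20)


@pytest.fixture(scope="session")
def study_occurrence(study_config):
    return synthetic.generate_occurrence(study_config)


@pytest.fixture(scope="session")
def study_consumption(study_config):
    return synthetic.generate_consumption(study_config)


@pytest.fixture(scope="session")
def reference_summaries():
    return defaults.reference_summaries()


def truncated_normal_moments(mean, sd, lo, hi):
    """Mean and sd of N(mean, sd) truncated to [lo, hi], by quadrature.

    Deliberately avoids scipy.stats.truncnorm and the package's rejection
    sampler: integrates the unnormalized parent density directly.
    """
    def pdf(x):
        return math.exp(-0.5 * ((x - mean) / sd) ** 2)

    z, _ = quad(pdf, lo, hi)
    m1, _ = quad(lambda x: x * pdf(x), lo, hi)
    m2, _ = quad(lambda x: x * x * pdf(x), lo, hi)
    mu = m1 / z
    var = m2 / z - mu * mu
    return mu, math.sqrt(var)


def brute_force_percentile(values, q):
    """Sort-and-interpolate percentile (linear, 'type 7')."""
    s = sorted(float(v) for v in values)
    if len(s) == 1:
        return s[0]
    h = (len(s) - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def published_di_values():
    """All DI values of the published intake grid, flattened."""
    return [
        v
        for cells in defaults.PUBLISHED_INTAKE.values()
        for pair in cells.values()
        for v in pair
    ]


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh deterministic stream
    return np.random.default_rng(7)
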