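import logging
import math

import numpy as np
import pytest

import lymphoref as lr

# the heavy warnings (small-group notices during repeated simulations) drown
# useful output; keep them out of the test log
logging.getLogger("lymphoref").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_spec():
    return lr.default_spec()


@pytest.fixture(scope="session")
def clean_cohort(default_spec):
    cohort, ledger = lr.generate_cohort(default_spec, seed=1)
    assert ledger.empty
    return cohort


@pytest.fixture(scope="session")
def established(clean_cohort):
    """One full pipeline run shared by the smoke-level assertions."""
    return lr.establish(clean_cohort)


def brute_rank_quantile(values, p):
    """Independent oracle for the rank rule r = p(n+1), linear interpolation,
    clamped to [1, n] — deliberately naive."""
    s = sorted(float(v) for v in values)
    n = len(s)
    r = p * (n + 1)
    r = min(max(r, 1.0), float(n))
    k = math.floor(r)
    frac = r - k
    if k >= n:
        return s[-1]
    return s[k - 1] + frac * (s[k] - s[k - 1])


def brute_tukey(values):
    """Independent fences oracle built on the brute quantile."""
    q1 = brute_rank_quantile(values, 0.25)
    q3 = brute_rank_quantile(values, 0.75)
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = [(v < lower) or (v > upper) for v in values]
    return lower, upper, mask
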