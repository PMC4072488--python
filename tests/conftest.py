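import numpy as np
import pytest

from cutscan.datagen import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config cohort (n=199), shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=199, seed=20240417))


@pytest.fixture(scope="session")
def big_cohort():
    """A large default-config cohort for scan-level checks."""
    return generate_cohort(GeneratorConfig(n_patients=2000, seed=915))


def small_survival_fixtures():
    """Hand-sized single-covariate datasets (<= 8 subjects) for oracle checks.

    Each is (time, event, x); includes censoring, ties, and tie-free cases
    but no separated designs (those are non-convergent by construction).
    """
    return [
        ([1, 2, 3], [1, 1, 0], [0, 1, 0]),
        ([1, 2, 3, 4], [1, 1, 1, 1], [1, 0, 1, 0]),
        ([1, 1, 2, 3], [1, 1, 1, 0], [1, 0, 0, 1]),
        ([2, 4, 4, 6, 8], [1, 0, 1, 1, 1], [0, 1, 1, 0, 1]),
        ([1, 2, 2, 2, 3, 5], [1, 1, 1, 0, 1, 1], [0.5, -1.0, 0.0, 2.0, 1.0, -0.5]),
        ([3, 1, 4, 1, 5, 9, 2, 6], [1, 0, 1, 1, 0, 1, 1, 1], [1, 1, 0, 0, 1, 0, 1, 0]),
        ([1, 1, 1, 2, 2, 3], [1, 1, 0, 1, 1, 1], [0, 1, 1, 1, 0, 0]),
        ([5, 4, 3, 2, 1], [1, 1, 1, 1, 1], [-1, 2, 0, 1, -2]),
    ]


def random_survival_data(rng, n=60, p=1, tied=False):
    """Random right-censored dataset with mild effects for property tests."""
    x = rng.normal(size=(n, p))
    t = rng.exponential(1.0 / np.exp(0.3 * x[:, 0]))
    c = rng.exponential(np.median(t) * 2, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    if tied:
        time = np.ceil(time * 4) / 4.0
    if event.sum() == 0:
        event[0] = 1
    return time, event, x
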