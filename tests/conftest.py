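import numpy as np
import pytest

from offload.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort shared across read-only tests."""
    cfg = CohortConfig(n_subjects=12, seed=42)
    trials, subjects = generate_cohort(cfg)
    return cfg, trials, subjects


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def make_correlated_pair(n, r, seed=0):
    """Two vectors whose *sample* Pearson correlation is exactly r."""
    g = np.random.default_rng(seed)
    x = g.standard_normal(n)
    z = g.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    z = z - z.mean()
    z = z - (z @ x) / (x @ x) * x  # orthogonalize to x
    z = z / z.std(ddof=1)
    y = r * x + np.sqrt(1 - r * r) * z
    return x, y


def vector_with_t(n, t, seed=0):
    """A length-n sample whose one-sample t statistic equals t exactly."""
    g = np.random.default_rng(seed)
    d = g.standard_normal(n)
    d = (d - d.mean()) / d.std(ddof=1)  # mean 0, sd 1
    return d + t / np.sqrt(n)  # mean t/sqrt(n), sd 1 -> t stat = t
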