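import numpy as np
import pytest

import jobsbayes as jb
from jobsbayes.data import RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sample():
    """A small simulated tissue sample with known truth (p=3, n=60)."""
    samples, truth = jb.simulate_dataset(jb.Scenario(p=3, n=60), seed=7)
    return samples[0], truth


@pytest.fixture(scope="session")
def short_fit():
    """One short fit shared by read-only downstream tests."""
    samples, truth = jb.simulate_dataset(jb.Scenario(p=3, n=80), seed=11)
    cfg = RunConfig(m=6, n_iter=200, n_burn=100, thin=2, seed=5)
    res = jb.SpatialCovarianceModel(samples[0]).fit(cfg)
    return samples[0], truth, res


def random_spd(rng, n, scale=1.0):
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))
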