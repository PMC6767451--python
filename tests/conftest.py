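import numpy as np
import pytest

import centilecharts as cc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def normal_chart_data():
    """Cross-sectional records from a normal truth with linear mean and SD."""
    rng = np.random.default_rng(101)
    n = 5000
    ga = rng.uniform(33.0, 42.0, n)
    mu = 10.0 + ga
    sd = 1.0 + 0.05 * ga
    y = rng.normal(mu, sd)
    return ga, y, (lambda t: 10.0 + t), (lambda t: 1.0 + 0.05 * t)


@pytest.fixture(scope="session")
def bccg_data():
    """Records from a BCCG truth with linear median, constant S and L."""
    rng = np.random.default_rng(202)
    n = 5000
    ga = rng.uniform(14.0, 42.0, n)
    params = (100.0 + 5.0 * ga, 0.08, 0.5)
    y = cc.family_quantile("BCCG", params, rng.uniform(1e-12, 1 - 1e-12, n))
    return ga, y, params


@pytest.fixture(scope="session")
def small_fetal():
    """A small longitudinal triplicate dataset with known components."""
    cfg = cc.LongConfig(n_subjects=300, seed=77)
    records, truth = cc.gen_fetal(cfg)
    return records, truth, cfg
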