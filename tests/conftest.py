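import numpy as np
import pytest

from culturewave import calibration
from culturewave.synthetic_data import Scenario, gen_calcurve, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def identity_curve():
    """Exact identity calibration curve (no wiggle, no curve error)."""
    return gen_calcurve(span=(6000.0, 9000.0), wiggle=0.0, error=0.0)


@pytest.fixture(scope="session")
def wiggly_curve():
    return gen_calcurve(span=(6000.0, 9000.0), wiggle=20.0, period=150.0, error=15.0)


@pytest.fixture(scope="session")
def default_dataset():
    """One strong-signal synthetic dataset shared across read-only tests."""
    scn = Scenario(seed=11)
    sites, specimens, curve, truth = generate_dataset(scn)
    return scn, sites, specimens, curve, truth


@pytest.fixture(scope="session")
def default_densities(default_dataset):
    _, sites, _, curve, _ = default_dataset
    return {
        row.site_id: calibration.calibrate(row.cra, row.cra_error, curve)
        for row in sites.df.itertuples()
    }


def random_distmatrix(rng, n, labels=None):
    """Distance matrix of random planar points (guaranteed metric)."""
    from culturewave.spatial_stats import DistMatrix

    pts = rng.uniform(0, 100, size=(n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistMatrix(d, tuple(labels or (f"s{i}" for i in range(n))))
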