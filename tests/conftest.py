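import numpy as np
import pytest

from trophiso.baselines import BaselineDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def plant_baseline(rng):
    """A mid-sized high-elevation plant δ¹⁵N baseline (n=20, ~7.6 ± 0.8 ‰)."""
    return BaselineDistribution(
        "4000-5000",
        "single",
        tuple(rng.normal(7.6, 0.8, 20)),
        tuple(rng.normal(-26.0, 1.5, 20)),
    )


@pytest.fixture
def consumer_csv(tmp_path):
    """A small well-formed consumer CSV with %C/%N columns."""
    text = (
        "sample_id,site_id,elevation_m,d13C,d15N,d34S,percent_C,percent_N\n"
        "m1,Site A,2500,-18.3,19.2,-1.6,42.0,10.0\n"
        "m2,Site A,2500,-19.1,18.0,-1.2,44.1,10.5\n"
        "m3,Site B,4600,-23.3,7.1,1.3,37.0,10.0\n"
    )
    path = tmp_path / "consumers.csv"
    path.write_text(text)
    return path
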