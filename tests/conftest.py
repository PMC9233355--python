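import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import poolrr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_map():
    """One chromosome, 11 equally spaced markers, 100 cM."""
    return poolrr.make_synthetic_map(1, 11, 10_000_000, 100.0, "uniform")


@pytest.fixture
def barley_map():
    """Three plateau-profile chromosomes, 150 cM / 400 Mb each."""
    return poolrr.make_synthetic_map(3, 400, 400_000_000, 450.0, "barley_like")


@pytest.fixture
def small_af_track():
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4 + ["chr2"] * 2,
            "pos_bp": [1_000, 101_000, 201_000, 301_000, 1_000, 51_000],
            "af": [0.52, 0.50, 0.60, 0.50, 0.45, 0.47],
        }
    )
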