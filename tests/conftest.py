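import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_atlas():
    """One-state two-region synthetic atlas with a planted exponent difference."""
    import renyispace as rs

    cfg = rs.SyntheticAtlasConfig(
        regions=("RegA", "RegB"), states=("W",),
        delta_k={("RegB", "W"): 1.0}, seed=7,
    )
    records, truth = rs.synthetic_atlas(cfg)
    return records, truth, cfg
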