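import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cropdyn import CovariateSpec, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def v_dataset():
    """Small vertical-form dataset with known ground truth."""
    cfg = SyntheticConfig(
        form="V", r_max=1.2, a=0.9, c=-7.9, b=0.3,
        covariate=CovariateSpec(name="Z", kind="lognormal", params=(0.0, 0.5)),
        noise_sd=0.05, n_blocks=6, n_cycles=10, seed=42,
        trend=(0.01, -0.0004),
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
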