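import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lld_edges() -> pd.DataFrame:
    """The 21-link disrupted-FC edge list of the LLD worked example."""
    from mmlfdr.datasets import lld_significant_links

    return lld_significant_links()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240404)


@pytest.fixture(scope="session")
def small_link_table() -> pd.DataFrame:
    """A 10-region (45-link), 8+8-subject synthetic table, 10% disrupted."""
    from mmlfdr import SubjectSimConfig, simulate_subjects

    table, _ = simulate_subjects(
        SubjectSimConfig(n_regions=10, n_per_group=8, prop_disrupted=0.1, seed=7)
    )
    return table
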