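import numpy as np
import pytest
from hypothesis import settings

from sweetspot import (InstrumentMetadata, compute_instruments,
                       default_config, generate_cohort)

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_cohort():
    """Default synthetic cohort (n=6000) with its truth registry."""
    cfg = default_config(n_participants=6000, seed=0)
    table, registry = generate_cohort(cfg)
    return cfg, table, registry


@pytest.fixture(scope="session")
def demo_scores(demo_cohort):
    _, table, _ = demo_cohort
    meta = InstrumentMetadata.for_synthetic_cohort()
    scores, cutoffs = compute_instruments(table, meta)
    return scores, cutoffs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
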