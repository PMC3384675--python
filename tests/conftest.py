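import numpy as np
import pytest
from hypothesis import settings

import optalign as oa

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_benchmark():
    """Reduced instance: 120 kbp database, 40 queries, 3 noise levels."""
    return oa.build_benchmark(db_size=120_000, n_queries=40, noise_levels=[0, 0.3, 0.6], seed=0)


@pytest.fixture(scope="session")
def small_report(small_benchmark):
    return oa.run_benchmark(small_benchmark)
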