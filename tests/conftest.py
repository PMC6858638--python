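import numpy as np
import pytest

from qtrimbench import (
    DecayParams,
    SimConfig,
    extract_amplicons,
    generate_references,
    make_pool,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_refs():
    """Eight synthetic references with embedded V3-V4 primer sites."""
    records = generate_references(8, rng_seed=11)
    amps, skipped = extract_amplicons(records)
    assert not skipped
    return amps


@pytest.fixture(scope="session")
def small_pool():
    return make_pool(30, 310, DecayParams(), rng_seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(small_refs, small_pool):
    """Two small simulated samples with gold standards."""
    cfg = SimConfig(
        n_samples=2,
        min_refs_per_sample=3,
        max_refs_per_sample=5,
        min_copies=1,
        max_copies=6,
        rng_seed=23,
    )
    return simulate_dataset(small_refs, small_pool, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
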