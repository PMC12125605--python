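"""Shared fixtures: one small simulated genome pair reused across test modules."""

import numpy as np
import pytest

from numtkit import synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.scaled_config(seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return synthetic.generate_genome(small_config)


@pytest.fixture(scope="session")
def small_scaffolds(small_truth):
    scaffolds, joins = synthetic.fragment_into_scaffolds(small_truth)
    return scaffolds, joins


@pytest.fixture(scope="session")
def small_reads(small_truth):
    return synthetic.simulate_reads(small_truth)


@pytest.fixture(scope="session")
def clean_truth():
    """Error-free small genome (for exact-recovery checks)."""
    cfg = synthetic.scaled_config(seed=11, error_rate=0.0)
    return synthetic.generate_genome(cfg)


@pytest.fixture(scope="session")
def clean_reads(clean_truth):
    return synthetic.simulate_reads(clean_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
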