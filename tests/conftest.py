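"""Shared fixtures.

The full dataset builds and cross-validations are expensive, so they are
session-scoped and shared between the unit and acceptance tests.  All
randomness is seeded; HR simulation itself is deterministic.
"""

import numpy as np
import pytest

import chaossensor as cs

SEED = 0


@pytest.fixture(scope="session")
def base1():
    """Full standard dataset at I_ex = 3.25 (10,000 x 50)."""
    return cs.build_base(1)


@pytest.fixture(scope="session")
def base2():
    """Full standard dataset at I_ex = 3.35 (10,000 x 50)."""
    return cs.build_base(2)


@pytest.fixture(scope="session")
def base12(base1, base2):
    return cs.merge_datasets(base1, base2)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small HR dataset for structural tests (fast)."""
    return cs.build_hr_dataset(
        i_ex=3.25, n_r=3, nl=20, s=4, windows_per_r=5, long_len=80
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
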