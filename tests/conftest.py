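"""Shared fixtures: synthetic experiments at two scales.

The full-size experiment (44 participants × 240 trials) is session-scoped
and shared by the acceptance checks; the small one keeps unit tests fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from fpdiag.synthetic_data import GeneratorParams, generate_experiment


@pytest.fixture(scope="session")
def full_table():
    """Default-condition experiment: 44 participants, 30 blocks × 8 trials."""
    return generate_experiment(GeneratorParams(seed=20260101))


@pytest.fixture(scope="session")
def small_table():
    """A fast 6-participant experiment for unit-level pipeline tests."""
    return generate_experiment(
        GeneratorParams(n_participants=6, n_blocks=12, trials_per_block=6, seed=99)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
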