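"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from prlkit.cohort import default_spec, generate_cohort, generate_study
from prlkit.task import TaskConfig


@pytest.fixture(scope="session")
def tiny_study():
    """4 subjects (2 per group) x 1 block: sub-second end-to-end data."""
    return generate_study(seed=101, n_audp=2, n_hc=2, task=TaskConfig(n_blocks=1))


@pytest.fixture(scope="session")
def small_group():
    """One 6-subject HC-like group x 1 block for quick inference tests."""
    spec = default_spec("HC", n_subjects=6, task=TaskConfig(n_blocks=1), seed=202)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
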