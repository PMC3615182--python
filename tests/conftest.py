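import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from gmvnet import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120 subjects, full 90-region parcellation, default (zero-change) truth."""
    return generate_cohort(CohortSpec(n_subjects=120, seed=42))


@pytest.fixture(scope="session")
def toy_cohort():
    """40 subjects, 20 regions: cheap input for end-to-end stages."""
    return generate_cohort(CohortSpec(n_subjects=40, n_regions=20, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
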