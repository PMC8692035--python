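import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers

from morphofit import (CohortParams, build_prsp,  # noqa: E402
                       generate_cohort, minimal_bounding_box, slice_volume)


@pytest.fixture(scope="session")
def small_cohort():
    """16 synthetic patients shared across read-only tests."""
    return generate_cohort(CohortParams(n=16, seed=3))


@pytest.fixture(scope="session")
def one_patient_sections():
    """Slice stack of one synthetic patient's left PRSP."""
    _, landmarks = generate_cohort(CohortParams(n=1, seed=7))
    vol = build_prsp(landmarks[0], "left")
    box = minimal_bounding_box(vol)
    return vol, box, slice_volume(vol, box)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
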