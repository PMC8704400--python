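import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from trampohar import Window, MotionLabel, generate_cohort_recordings


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_window(rng):
    return Window(rng.normal(0, 0.5, (64, 3)), MotionLabel.TJ, "A", 1)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 5 sets x 6 motions, 2 s bouts: small enough for fast
    evaluation-layer tests, with every set index present."""
    profiles, recordings = generate_cohort_recordings(
        n_subjects=3, n_sets=5, seed=11, duration_s=2.0
    )
    return recordings
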