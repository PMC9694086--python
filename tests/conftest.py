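"""Shared fixtures.

The expensive cohort experiment (30 subjects, three censoring variants)
is session-scoped so the group-level directional checks and the distance
-profile checks all share one computation.
"""

import numpy as np
import pytest

from scrubkit import phantom, pipeline


@pytest.fixture(scope="session")
def template():
    """Default-resolution phantom template with 16 nodes."""
    return phantom.make_phantom((32, 32, 24), 2.5, 16, seed=7)


@pytest.fixture(scope="session")
def small_template():
    """Cheap low-resolution template for fast unit tests."""
    return phantom.make_phantom((20, 20, 16), 2.5, 4, seed=3)


@pytest.fixture(scope="session")
def cohort30():
    """The confounded synthetic cohort used for the group-level checks."""
    return phantom.simulate_cohort(
        n_subjects=30, runs_per_subject=2, n_frames=330,
        confound_strength=1.0, seed=101)


@pytest.fixture(scope="session")
def cohort30_sweep(cohort30):
    """Pipeline sweep over no censoring, 0.5 mm and 0.3 mm."""
    cfg = pipeline.PipelineConfig()
    return pipeline.sweep_thresholds(cfg, cohort30, thresholds=[0.5, 0.3])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
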