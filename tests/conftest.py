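"""Shared fixtures: one fully analysed synthetic assay reused across tests.

The standard fixture is a control-cohort simulation at the default
160x192 geometry, rendered with noise_sd=4 and analysed by the vision
stage; session scope keeps the expensive render/detect chain to a single
run for the whole suite.
"""

import numpy as np
import pytest

import conetrace as ct
from conetrace.pipeline import PRESETS, default_geometry, fast_geometry


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def control_truth(geometry):
    return ct.simulate_cohort(PRESETS["control"].with_seed(11), geometry)


@pytest.fixture(scope="session")
def control_frames(control_truth, geometry):
    return ct.render_video(control_truth, geometry, seed=12)


@pytest.fixture(scope="session")
def control_series(control_frames):
    return ct.analyze_recording(control_frames, min_area=8)


@pytest.fixture(scope="session")
def small_geometry():
    return fast_geometry()


@pytest.fixture(scope="session")
def knockdown_truths(small_geometry):
    """Five replicate high-toxicity simulations (pronounced knockdown)."""
    return [
        ct.simulate_cohort(PRESETS["knockdown_prone"].with_seed(100 + i), small_geometry)
        for i in range(5)
    ]
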