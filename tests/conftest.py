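"""Shared fixtures: small geometries and the planted-recovery cohort.

The recovery cohort (5 subjects x 4 runs on the default 24^3 grid) is
expensive, so it is simulated and preprocessed once per session and
shared by every test that needs realistic end-to-end data.
"""

import numpy as np
import pytest

from persotarget.pipeline import PipelineConfig, derive_targets, preprocess_cohort
from persotarget.synthetic_data import CohortSpec, make_masks, simulate_cohort
from persotarget.volumetric_io import VolumeGeometry


@pytest.fixture
def small_geom():
    """8^3 grid of 2-mm voxels centered on the world origin."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -7.0
    return VolumeGeometry(dims=(8, 8, 8), affine=affine)


@pytest.fixture
def mni_like_geom():
    """Grid whose world extent covers the left-DLPFC sphere centers."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = (-70.0, 0.0, 10.0)
    return VolumeGeometry(dims=(36, 36, 36), affine=affine)


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(n_subjects=5, seed=1)


@pytest.fixture(scope="session")
def default_masks(default_spec):
    return make_masks(default_spec)


@pytest.fixture(scope="session")
def recovery_cohort(default_spec):
    """Simulated + preprocessed 5-subject cohort with derived targets."""
    runs, truths, masks = simulate_cohort(default_spec)
    config = PipelineConfig()
    cleaned = preprocess_cohort(runs, masks, config)
    quads = derive_targets(cleaned, masks, config)
    return {
        "runs": runs,
        "cleaned": cleaned,
        "truths": truths,
        "masks": masks,
        "quads": quads,
        "config": config,
    }
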