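import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from lcgrad import phantom
from lcgrad.volumes import CoordinateTable

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_config() -> phantom.PhantomConfig:
    return phantom.PhantomConfig(n_timepoints=150, seed=0)


@pytest.fixture(scope="session")
def geometry(base_config):
    """Shared phantom mask, atlas and coordinate table."""
    mask, affine = phantom.make_phantom_roi(base_config)
    atlas = phantom.make_phantom_atlas(base_config, mask)
    coords = CoordinateTable.from_mask(mask)
    return mask, atlas, coords


@pytest.fixture(scope="session")
def noiseless_subject(base_config, geometry):
    mask, atlas, coords = geometry
    cfg = dataclasses.replace(base_config, noise_sd=0.0, seed=11)
    roi_ts, parcel_ts, labels, truth = phantom.simulate_subject_timeseries(
        cfg, mask, atlas, coords
    )
    return cfg, roi_ts, parcel_ts, labels, truth


@pytest.fixture(scope="session")
def small_cohort() -> phantom.Cohort:
    return phantom.simulate_cohort(40, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
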