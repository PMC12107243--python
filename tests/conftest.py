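import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny effect-free cohort shared by pipeline-level tests."""
    from voxelgraph.synthetic import SyntheticConfig, simulate_cohort

    cfg = SyntheticConfig(grid_shape=(8, 8, 8),
                          group_sizes={"FND": 6, "PC": 6, "HC": 6},
                          n_timepoints=140, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    from voxelgraph.pipeline import Dataset

    c = small_cohort
    return Dataset(images=c.images, motion=c.motion_tables, mask=c.mask,
                   parcellation=c.parcellation, affine=c.affine,
                   subjects=c.subjects, tr_seconds=c.config.tr_seconds,
                   noise_rois=c.noise_rois)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
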