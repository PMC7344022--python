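import numpy as np
import pytest

import sampenmap as sm


@pytest.fixture
def rng():
    return np.random.default_rng(20201907)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small effect cohort shared by aggregation/stats tests.

    4 subjects, short series, all three ROI classes present.
    """
    cfg = sm.CohortConfig(
        n_subjects=4,
        parcels=sm.demo_parcels(network_voxels=10, region_voxels=6),
        grid_shape=(6, 6, 4),
        n_timepoints=80,
        seed=11,
    )
    scans, atlas, truth = sm.simulate_cohort(cfg)
    return cfg, scans, atlas, truth


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    cfg, scans, atlas, truth = tiny_cohort
    mask = atlas.mask()
    maps = [(sm.sample_entropy_map(vol, mask), md) for vol, md in scans]
    return sm.build_cohort_table(maps, atlas)
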