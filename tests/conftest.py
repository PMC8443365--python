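import numpy as np
import pytest

from fcdegree.imaging_io import BoldRun, MaskVolume
from fcdegree.synthcohort import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sim_config():
    """Desk-scale cohort for fast unit tests (not the acceptance scale)."""
    return SimulationConfig(
        grid_shape=(8, 8, 8),
        n_timepoints=60,
        n_patients=4,
        n_controls=4,
        n_hub_voxels=8,
        seed=99,
    )


@pytest.fixture
def tiny_mask():
    mask = np.zeros((4, 1, 1), dtype=bool)
    mask[:, 0, 0] = True
    return MaskVolume(data=mask, affine=np.eye(4))


def make_run(data, tr=2.0, affine=None, subject_id="test"):
    if affine is None:
        affine = np.eye(4)
    return BoldRun(data=np.asarray(data, float), tr_seconds=tr, affine=affine,
                   subject_id=subject_id)


@pytest.fixture
def random_run(rng):
    data = rng.standard_normal((6, 6, 6, 40))
    return make_run(data)


@pytest.fixture
def full_mask_6():
    return MaskVolume(data=np.ones((6, 6, 6), bool), affine=np.eye(4))
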