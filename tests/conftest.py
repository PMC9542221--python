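import numpy as np
import pytest

from qmrsynth.phantom import CohortSpec, generate_cohort, generate_phantom, simulate_subject_images
from qmrsynth.physics import RelaxometryMaps, default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def uniform_maps():
    """Homogeneous 4x4x2 phantom: T1 1000 ms, T2 100 ms, PD 1."""
    shape = (4, 4, 2)
    return RelaxometryMaps(np.full(shape, 1000.0), np.full(shape, 100.0),
                           np.ones(shape), np.ones(shape, bool))


@pytest.fixture(scope="session")
def tiny_record(protocol):
    """One small noiseless phantom with all four weighted contrasts."""
    rec = generate_phantom(seed=7, grid_shape=(32, 32, 10))
    return simulate_subject_images(rec, protocol, noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight noiseless subjects with images and survival (desk scale)."""
    spec = CohortSpec(n_subjects=8, grid_shape=(32, 32, 10), seed=5,
                      noise_sigma=0.0)
    records, table = generate_cohort(spec)
    return records, table
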