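import numpy as np
import pytest

from lispcn.network import ArchConfig, build_bundle
from lispcn.phantom import LinkParams, PhantomSpec, generate_cohort, generate_pair


@pytest.fixture(scope="session")
def small_cohort():
    """24 phantom patients x 2 slices at 32x32 — cheap shared fixture."""
    return generate_cohort(24, 0.25, 32, seed=11, slices_per_patient=2)


@pytest.fixture(scope="session")
def tiny_bundle():
    return build_bundle(ArchConfig(), seed=3)


@pytest.fixture()
def noise_free_spec():
    return PhantomSpec(image_size=64, tumor_center=(32.0, 30.0),
                       tumor_axes=(10.0, 6.0), tumor_angle=0.4,
                       enhancement=(0.2, 0.8, 0.5), shrinkage=0.5,
                       noise_sigma=0.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
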