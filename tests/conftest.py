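import numpy as np
import pytest

from fdgasym.config import config_from_dict
from fdgasym.kinetics import KineticParams, PlasmaInput
from fdgasym.phantom import PhantomSpec, build_labels


@pytest.fixture(scope="session")
def feng_input():
    return PlasmaInput()


@pytest.fixture(scope="session")
def gm_kinetics():
    """Default gray-matter rate constants."""
    return KineticParams(K1=0.102, k2=0.130, k3=0.062)


@pytest.fixture(scope="session")
def ez_kinetics(gm_kinetics):
    """Hypometabolic epileptogenic-zone variant (reduced transport and k3)."""
    return gm_kinetics.scaled(K1_factor=0.92, k3_factor=0.75)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom for fast voxelwise tests."""
    return PhantomSpec(shape=(24, 24, 16), voxel_mm=4.0, n_regions=2, noise_sigma=0.05)


@pytest.fixture(scope="session")
def small_labels(small_spec):
    return build_labels(small_spec)


@pytest.fixture(scope="session")
def default_labels():
    return build_labels(PhantomSpec())


@pytest.fixture
def small_cohort_config(small_spec):
    cfg = config_from_dict({"cohort": {"n": 4}})
    from dataclasses import replace

    return replace(cfg.cohort, spec=small_spec)
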