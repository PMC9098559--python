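import numpy as np
import pytest

from pfnets import synthetic as syn


@pytest.fixture(scope="session")
def mesh1():
    """42-vertex icosphere."""
    return syn.build_sphere_mesh(1)


@pytest.fixture(scope="session")
def mesh2():
    """162-vertex icosphere (desk-scale surface)."""
    return syn.build_sphere_mesh(2)


@pytest.fixture(scope="session")
def hierarchy2(mesh2):
    return syn.make_hierarchy_map(mesh2, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """Small full forward simulation shared across tests."""
    cfg = syn.SyntheticConfig(n_subjects=8, subdivisions=1, T=150,
                              scales=(2, 3, 4), seed=42)
    return syn.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
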