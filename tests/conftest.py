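import numpy as np
import pytest

from femrec import phantom as ph
from femrec import ssam


@pytest.fixture(scope="session")
def default_params():
    return ph.PhantomParams()


@pytest.fixture(scope="session")
def default_phantom(default_params):
    """Default phantom at full resolution: (mesh, landmarks)."""
    return ph.generate_phantom(default_params, mesh_resolution=1)


@pytest.fixture(scope="session")
def coarse_phantom(default_params):
    return ph.generate_phantom(default_params, mesh_resolution=0)


@pytest.fixture(scope="session")
def small_population():
    """8 coarse phantoms with volumes; shared by the model-building tests."""
    return ph.sample_population(8, seed=3, mesh_resolution=0, voxel_spacing=2.5)


@pytest.fixture(scope="session")
def corresponded_tets(small_population):
    """Per-specimen tet meshes (generator correspondence) with mapped HU."""
    out = []
    for s in small_population:
        tm = ph.phantom_tet_mesh(s.params, mesh_resolution=0)
        out.append(ssam.map_appearance(tm, s.volume))
    return out


@pytest.fixture(scope="session")
def small_model(corresponded_tets):
    return ssam.build_ssam(corresponded_tets, use_appearance=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
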