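import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from tomomatch import (
    PhantomSpec,
    Template,
    Volume,
    make_mask,
    make_phantom,
    make_wedge_list,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_volume(rng):
    """A 16^3 noise volume at 8.704 A/voxel."""
    return Volume(rng.normal(size=(16, 16, 16)).astype(np.float32), 8.704)


@pytest.fixture(scope="session")
def ball_template():
    return make_phantom(PhantomSpec(kind="ball", dims=24))


@pytest.fixture(scope="session")
def two_lobe_template():
    return make_phantom(PhantomSpec(kind="two_lobe", dims=24))


@pytest.fixture(scope="session")
def wedge_list_60():
    """±60° single-axis scheme, 3° steps (41 tilts)."""
    return make_wedge_list()


@pytest.fixture
def simple_template(rng):
    """Random 8^3 template with a spherical binary mask (for oracle tests)."""
    tmap = Volume(rng.normal(size=(8, 8, 8)).astype(np.float32), 1.0)
    mask = make_mask("sphere", 7.0, 1.0, 8, taper=0.0)
    return Template(map=tmap, mask=mask)
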