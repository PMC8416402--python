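import numpy as np
import pytest

from ldctgan.phantom import (PhantomSpec, Ellipse, DoseParams, make_phantom,
                             build_dataset, SHEPP_LOGAN_ELLIPSES)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def shepp_logan_96():
    """Normalized Shepp-Logan head phantom on a 96x96 grid."""
    img = make_phantom(PhantomSpec([Ellipse(*e) for e in SHEPP_LOGAN_ELLIPSES],
                                   grid_size=96)).pixels
    return (img - img.min()) / (img.max() - img.min())


@pytest.fixture(scope="session")
def disk_spec():
    return PhantomSpec([Ellipse(0.0, 0.0, 0.5, 0.5, 0.0, 1.0)], grid_size=64)


@pytest.fixture(scope="session")
def desk_dataset():
    """16 + 4 paired phantoms at the desk-profile low dose; shared across
    tests that only read it."""
    return build_dataset(16, 4, DoseParams(incident_photons=1e3),
                         seed=11, grid_size=64)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small dataset for fast training-loop plumbing tests."""
    return build_dataset(4, 2, DoseParams(incident_photons=1e3),
                         seed=23, grid_size=48)
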