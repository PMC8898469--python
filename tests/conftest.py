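import numpy as np
import pytest

from glymphkit import AcquisitionProtocol
from glymphkit.phantom import default_phantom_spec, make_brain_phantom
from glymphkit.micrograph import MicrographSpec, VesselSpec


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def small_spec():
    return default_phantom_spec((40, 40, 40), seed=11)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return make_brain_phantom(small_spec)


@pytest.fixture(scope="session")
def three_vessel_spec():
    return MicrographSpec(
        image_shape_px=(512, 512),
        vessels=(
            VesselSpec((50.0, 50.0), 6.0, pi_true=12.0, radial_cv_true=0.0),
            VesselSpec((120.0, 110.0), 20.0, wall_thickness_um=2.5,
                       pi_true=6.0, radial_cv_true=0.3),
            VesselSpec((60.0, 140.0), 8.0, pi_true=8.0,
                       radial_cv_true=0.15, phase_deg=40.0),
        ),
        seed=5,
    )


@pytest.fixture(scope="session")
def speckle_mask():
    """Binary mask covering exactly 7.00% of a 1500x1500 px field."""
    rng = np.random.default_rng(0)
    mask = np.zeros((1500, 1500), dtype=bool)
    idx = rng.choice(mask.size, int(0.07 * mask.size), replace=False)
    mask.ravel()[idx] = True
    return mask
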