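import numpy as np
import pytest

from pleuraquant.io import CTVolume, LabelMask
from pleuraquant.phantom import PhantomSpec, SideSpec, generate_phantom


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(data, dtype=np.float32), spacing)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    return LabelMask(np.asarray(data, dtype=np.uint8), spacing)


@pytest.fixture(scope="session")
def bilateral_phantom():
    """One fully featured bilateral phantom shared across tests."""
    spec = PhantomSpec(
        right=SideSpec(
            effusion_ml=60.0, density_hu=8.0,
            inclusions=[(4.0, 60.0, "cavity")], gas_bubbles_ml=[3.0],
        ),
        left=SideSpec(
            effusion_ml=20.0, geometry="loculated_lens",
            rim_width_mm=4.0, pneumothorax_ml=20.0,
        ),
        seed=3,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def plain_phantom():
    """A single unilateral serous effusion, no complexity features."""
    spec = PhantomSpec(right=SideSpec(effusion_ml=45.0, density_hu=10.0),
                       seed=5)
    return generate_phantom(spec)
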