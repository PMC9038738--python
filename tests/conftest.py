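import numpy as np
import pytest

from radialign import WeightWindow, compute_gradients, structure_tensor
from radialign.synthetic import FiberFieldSpec, make_grating


@pytest.fixture
def grating30():
    """Noise-free 256x256 sinusoidal grating, stripe axis 30 deg."""
    return make_grating(
        FiberFieldSpec(height=256, width=256, stripe_angle_deg=30.0, wavelength_px=16.0)
    )


@pytest.fixture
def whole_window():
    """Box window covering the full 256x256 frame."""
    return WeightWindow(center=(127.5, 127.5), size_L=256)


def tensor_of(image, window, sigma=1.5):
    return structure_tensor(compute_gradients(image, sigma=sigma), window)
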