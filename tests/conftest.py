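import numpy as np
import pytest

from fazseg import GrayImage, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def clean_phantom():
    """One artifact-free 3 mm superficial phantom with its truth mask."""
    spec = PhantomSpec(field_mm=3.0, faz_radius_mm=0.32, irregularity=0.15,
                       depth_style="superficial", seed=11)
    img, gt = generate_phantom(spec)
    return img, gt, spec


@pytest.fixture(scope="session")
def artifact_phantom():
    """A phantom with a dark acquisition-artifact band along one border."""
    spec = PhantomSpec(field_mm=3.0, faz_radius_mm=0.30, irregularity=0.2,
                       artifact_band=True, seed=5)
    img, gt = generate_phantom(spec)
    return img, gt, spec


def make_gray(pixels, field_mm=3.0):
    return GrayImage(np.asarray(pixels, dtype=float), field_mm=field_mm)
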