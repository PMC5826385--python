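import numpy as np
import pytest

from brainshift import boundary, mesh as bmesh
from brainshift.material import OgdenPronyMaterial
from brainshift.pulse import generate_pulse


@pytest.fixture(scope="session")
def material():
    return OgdenPronyMaterial()


@pytest.fixture(scope="session")
def standard_pulse():
    """A ~52 rad/s, 65 degree pulse with 60 pre-motion video frames."""
    return generate_pulse(52.0, 8.6e3, 8.5e3, np.deg2rad(65.0), pad_before=0.024)


@pytest.fixture(scope="session")
def gentle_pulse():
    """A slower, smaller-angle pulse for stiff/rigid-limit runs."""
    return generate_pulse(30.0, 6.0e3, 6.0e3, 0.5, pad_before=0.024, pad_after=0.005)


@pytest.fixture(scope="session")
def sagittal_mesh():
    return bmesh.build_geometry("sagittal", target_edge=5.0)


@pytest.fixture(scope="session")
def circle_mesh():
    return bmesh.build_geometry("circle", target_edge=6.0, radius=25.0)


@pytest.fixture(scope="session")
def sagittal_veins(sagittal_mesh):
    return boundary.place_bridging_veins(sagittal_mesh)
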