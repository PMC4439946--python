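import numpy as np
import pytest

from detem.grids import DensityVolume
from detem.phantom import PhantomSpec, assign_materials, make_phantom


@pytest.fixture(scope="session")
def water_box():
    """Uniform water box: 120 x 160 x 80 mm at 2 mm spacing."""
    data = np.full((60, 80, 40), 1.0, dtype=np.float32)
    dv = DensityVolume(data=data, spacing=(2.0, 2.0, 2.0),
                       origin=(-59.0, -79.0, -39.0))
    return dv, assign_materials(dv)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: 80 mm body, 12 mm CTV, abutting 12 mm air cavity."""
    return PhantomSpec(body_radius=40.0, body_length=60.0, ctv_radius=12.0,
                       cavity_center=(-24.0, 0.0, 0.0), cavity_radius=12.0,
                       spacing=(3.0, 3.0, 3.0), air_pad=6.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    dv, structures = make_phantom(small_spec)
    return dv, assign_materials(dv), structures


@pytest.fixture(scope="session")
def small_phantom_fine(small_spec):
    """Same geometry at 2 mm spacing (sharper cavity rim)."""
    spec = PhantomSpec(**{**small_spec.__dict__, "spacing": (2.0, 2.0, 2.0)})
    dv, structures = make_phantom(spec)
    return dv, assign_materials(dv), structures
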