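import numpy as np
import pytest

from sphenoscore.phantoms import PhantomSpec, make_phantom, straight_artery


@pytest.fixture(scope="session")
def wrap180_phantom():
    """One 180-degree wrap phantom with narrowing, CS overlap and bone contact."""
    spec = PhantomSpec(
        grid_shape=(96, 96, 96),
        tumor_kind="annular_wrap",
        arteries=[straight_artery("M1", 48, 48, (14, 82), narrowing_fraction=0.3)],
        wrap_angle_deg=180,
        cs_overlap_voxels=250,
        bone_contact=True,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def sphere_phantom_halfmm():
    """10 mm-radius sphere voxelized at 0.5 mm spacing."""
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        spacing_mm=(0.5, 0.5, 0.5),
        tumor_kind="ellipsoid",
        tumor_semiaxes_mm=(10, 10, 10),
    )
    return make_phantom(spec)


@pytest.fixture
def cylinder_mask():
    """Straight z-axis cylinder, radius 3 mm at 1 mm spacing."""
    m = np.zeros((40, 40, 60), dtype=bool)
    ii, jj = np.mgrid[0:40, 0:40]
    disk = (ii - 20) ** 2 + (jj - 20) ** 2 <= 9
    m[:, :, 5:55] = disk[:, :, None]
    return m
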