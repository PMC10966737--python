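import numpy as np
import pytest

from enamelmap.config import PipelineConfig
from enamelmap.geometry import DetectorGeometry, ImagingGeometry, RasterGrid
from enamelmap.phantom import build_enamel_phantom
from enamelmap.simulate import ReflectionList


@pytest.fixture(scope="session")
def desk_detector() -> DetectorGeometry:
    """Mapping-mode detector geometry used by the desk-scale scene."""
    return DetectorGeometry(energy=18.0, distance=9.6, beam_center=(127.5, 127.5))


@pytest.fixture(scope="session")
def compact_detector() -> DetectorGeometry:
    """Short-distance geometry fitting all apatite rings on a 128 px detector."""
    return DetectorGeometry(energy=18.0, distance=4.8, beam_center=(63.5, 63.5))


@pytest.fixture(scope="session")
def hap() -> ReflectionList:
    return ReflectionList.hydroxyapatite()


@pytest.fixture(scope="session")
def lab6() -> ReflectionList:
    return ReflectionList.lab6()


@pytest.fixture(scope="session")
def desk_phantom():
    """Desk-scale enamel slab with a lesion window at the +x face."""
    return build_enamel_phantom(
        (128, 96, 128), 2.0, rod_pitch=5.0,
        window=((184.0, 205.0), (60.0, 140.0), (100.0, 160.0)), seed=1,
    )


@pytest.fixture
def tiny_imaging() -> ImagingGeometry:
    return ImagingGeometry(pixel_size=1.0, n_u=96, n_v=32,
                           angle_list=np.array([0.0, 90.0, 180.0]))


@pytest.fixture
def small_grid() -> RasterGrid:
    return RasterGrid(origin=(20.0, 10.0), step=(24.0, 20.0), counts=(4, 3),
                      beam_size=(10.0, 10.0))


def make_slab_phantom(mu_mineral=2.0e-3, density=0.5, shape=(64, 32, 64),
                      x_range=(16, 48), z_range=(20, 40), voxel=1.0):
    """Homogeneous rectangular slab with known attenuation (closed-form tests)."""
    from enamelmap.phantom import LBL_INTER_ROD, Phantom

    vals = np.zeros(shape, dtype=np.float32)
    vals[x_range[0]: x_range[1], :, z_range[0]: z_range[1]] = density
    labels = np.zeros(shape, dtype=np.uint8)
    labels[vals > 0] = LBL_INTER_ROD
    return Phantom(density=vals, labels=labels, voxel_size=voxel, mu_mineral=mu_mineral)
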