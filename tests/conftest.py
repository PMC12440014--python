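import numpy as np
import pytest

from laminalpha import laminar as lm
from laminalpha import synthdata as sd
from laminalpha.core import Paradigm
from laminalpha.pipeline import PipelineConfig, make_geometry


@pytest.fixture(scope="session")
def paradigm() -> Paradigm:
    return Paradigm()


@pytest.fixture(scope="session")
def annulus_geometry():
    """Full-annulus desk-scale geometry shared across tests (read-only)."""
    cfg = PipelineConfig()
    return make_geometry(cfg)


@pytest.fixture(scope="session")
def quarter_ribbon():
    return sd.make_ribbon(10, 16, arc=np.pi / 2, thickness_slices=4)


@pytest.fixture(scope="session")
def slab_geometry():
    """Flat slab: WM below, 6 GM layers, CSF above (zero curvature)."""
    lab = np.zeros((8, 20, 14), dtype=int)
    lab[:, :, 0:4] = 2
    lab[:, :, 4:10] = 3
    lab[:, :, 10:14] = 1
    geom = sd.LabelledVolume(lab)
    depths = lm.compute_depths(geom)
    return geom, depths


def radius_map(geom):
    """In-plane radius of every voxel of an annulus geometry."""
    half = geom.meta["center"][0]
    yy, xx = np.meshgrid(
        np.arange(geom.shape[0]) - half, np.arange(geom.shape[1]) - half, indexing="ij"
    )
    return np.repeat(np.hypot(xx, yy)[:, :, None], geom.shape[2], axis=2)
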