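import numpy as np
import pytest

from nodenet3d.io import AnnotatedVolume, Covariates, NodeSegmentation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere_volume():
    """A 12 mm sphere of soft tissue in fat, at 0.75 x 0.75 x 3.0 mm spacing."""
    shape = (48, 48, 12)
    spacing = (0.75, 0.75, 3.0)
    center = np.array([24, 24, 6])
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    mm = [(g - c) * s for g, c, s in zip(grids, center, spacing)]
    r = np.sqrt(sum(x**2 for x in mm))
    voxels = np.where(r <= 6.0, 60.0, -100.0).astype(np.float32)
    mask = r <= 6.0
    node = NodeSegmentation(mask=mask, label="nm_no_ene", node_id="s1")
    return AnnotatedVolume(
        voxels=voxels,
        spacing=spacing,
        patient_id="pt0",
        nodes=[node],
        covariates=Covariates(hpv_p16=1, primary_site="oropharynx"),
    )


@pytest.fixture
def random_volume(rng):
    voxels = rng.normal(0, 50, size=(20, 20, 8)).astype(np.float32)
    mask = np.zeros((20, 20, 8), dtype=bool)
    mask[8:14, 7:13, 3:6] = True
    node = NodeSegmentation(mask=mask, label="negative", node_id="r1")
    return AnnotatedVolume(voxels=voxels, spacing=(1.0, 1.0, 2.0), patient_id="pt1", nodes=[node])
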