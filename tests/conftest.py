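import numpy as np
import pytest

from exmkit.fixtures import (
    CompartmentSpec,
    DistortionSpec,
    PSFModel,
    SceneSpec,
    build_scene,
    render_volume,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere_puncta():
    """500 puncta exactly on a 150 nm sphere centered at (500,500,500)."""
    r = np.random.default_rng(42)
    v = r.standard_normal((500, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return 150.0 * v + 500.0


@pytest.fixture(scope="session")
def textured_volume_pair():
    """Pre/post volume pair with a compartment and a known radial
    under-expansion field (amplitude -0.1, falloff 300 nm)."""
    shape = (72, 72, 72)
    voxel = 20.0
    extent = shape[0] * voxel
    center = (extent / 2,) * 3
    dist = DistortionSpec(
        global_factor=1.0, local_centers=(center,), local_amplitude=-0.1, local_falloff=300.0
    )
    comp = CompartmentSpec(centroid=center, radii=(100.0, 100.0, 100.0),
                           n_membrane_puncta=150, n_interior_puncta=0)
    spec = SceneSpec(
        compartments=(comp,), distortion=dist, n_background_puncta=1500,
        background_low=(50.0,) * 3, background_high=(extent - 50.0,) * 3,
    )
    gt = build_scene(spec, seed=5)
    psf = PSFModel(60.0, 120.0)
    pre = render_volume(gt.all_points("pre"), 1.0, psf, shape, (voxel,) * 3, allow_clipping=True)
    post = render_volume(gt.all_points("post"), 1.0, psf, shape, (voxel,) * 3, allow_clipping=True)
    return pre, post, gt, dist, center
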