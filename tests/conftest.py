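import numpy as np
import pytest

from dynfet.parametric import ParametricImage, VoxelMask
from dynfet.synthetic import CohortSpec, iter_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One noise-free phantom patient, shared across tests."""
    spec = CohortSpec(n_patients=2, wildtype_fraction=0.5, seed=11, noise_sd=0.0)
    return next(iter_phantom(spec))


def random_blob_fixture(rng, max_extent=14, spacing=(2.03, 2.03, 2.03)):
    """A random intensity image plus a random connected-ish mask."""
    shape = tuple(int(x) for x in rng.integers(7, max_extent, 3))
    img = rng.normal(2.0, 0.8, shape)
    centre = np.array([s / 2 for s in shape])
    radii = rng.uniform(2.0, np.array(shape) / 2.2)
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    mask = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii)) <= 1.0
    # roughen the boundary so masks are not perfect ellipsoids
    noise = rng.random(shape) < 0.1
    mask = mask & ~noise
    if not mask.any():
        mask[tuple(int(c) for c in centre)] = True
    image = ParametricImage(img, "TBR_20_40", spacing)
    return image, VoxelMask(mask)
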