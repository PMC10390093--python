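import numpy as np
import pytest

from fracmorph.synthetic import ShapeSpec, gen_tumor_mask
from fracmorph.types import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tumor_mask():
    """A moderately rough tumor-like blob on the default canvas."""
    return gen_tumor_mask(ShapeSpec(
        kind="tumor", depth_or_size=256, seed=1,
        params={"base_radius": 40, "roughness_amplitude": 0.3,
                "roughness_frequency": 10, "n_branches": 2,
                "branch_length": 20}))


def random_blob(rng, size=24, p=0.35, smooth=True):
    """A random binary blob for morphology property tests.

    ``smooth=True`` gives segmentation-mask-like shapes (correlated noise
    thresholded, the skimage binary_blobs model); ``smooth=False`` gives raw
    pixel noise for oracle tests that want adversarial patterns.
    """
    if smooth:
        from skimage.data import binary_blobs
        raw = binary_blobs(length=size, blob_size_fraction=0.15,
                           volume_fraction=p, rng=int(rng.integers(2 ** 31)))
    else:
        raw = rng.random((size, size)) < p
    if not raw.any():
        raw[size // 2, size // 2] = True
    return BinaryMask(raw)
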