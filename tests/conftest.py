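import numpy as np
import pytest

from petseval.core import AnalysisROI, PETVolume, SegmentationMask
from petseval.phantom import PhantomSpec, make_record


@pytest.fixture(scope="session")
def noisy_record():
    """One realistic phantom case: blurred, noisy, textured 30 mm sphere."""
    spec = PhantomSpec(
        equivalent_diameter=30.0,
        tumor_suv_mean=6.0,
        background_suv=1.0,
        intratumor_texture_sd=0.5,
        psf_fwhm=(7.0, 7.0, 7.0),
        noise_sd=0.3,
        voxel_spacing=(3.0, 3.0, 3.0),
        grid_shape=(64, 64, 48),
        seed=42,
    )
    return make_record(spec)


@pytest.fixture
def disk_volume():
    """Noiseless 10:1-contrast disk (radius 10 voxels) stacked on 3 slices."""
    shape = (48, 48, 3)
    vol = np.ones(shape)
    x, y = np.mgrid[:48, :48]
    disk = (x - 24) ** 2 + (y - 24) ** 2 <= 100
    vol[disk] = 10.0
    truth = np.repeat(disk[:, :, None], 3, axis=2)
    return (
        PETVolume(vol, (1.0, 1.0, 1.0)),
        SegmentationMask(truth, (1.0, 1.0, 1.0)),
        AnalysisROI((0, 0, 0), shape),
    )


def random_mask_pair(rng, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    """A pair of random nonempty masks on a small grid."""
    while True:
        a = rng.random(shape) < rng.uniform(0.05, 0.5)
        b = rng.random(shape) < rng.uniform(0.05, 0.5)
        if a.any() and b.any():
            return (
                SegmentationMask(a, spacing),
                SegmentationMask(b, spacing),
            )
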