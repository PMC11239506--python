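import numpy as np
import pytest

from wfdecon import OpticalParams, PSFVolume, pixel_integrated_psf


@pytest.fixture(scope="session")
def optics() -> OpticalParams:
    """High-NA oil objective, cyan emission, 130 nm voxels."""
    return OpticalParams(na=1.45, ni=1.515, lambda_em=460.0, dxy=130.0, dz=130.0)


@pytest.fixture(scope="session")
def bw_psf_small(optics) -> PSFVolume:
    """A small Born-Wolf PSF for fast deconvolution tests."""
    return pixel_integrated_psf(optics, (21, 21, 15))


def make_gaussian_psf(shape=(9, 9, 9), sigma=1.5, voxel=(130.0, 130.0, 130.0)) -> PSFVolume:
    """Separable Gaussian test kernel satisfying the PSF invariants."""
    axes = []
    for n in shape:
        c = (n - 1) / 2
        x = np.arange(n) - c
        axes.append(np.exp(-0.5 * (x / sigma) ** 2))
    data = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    data /= data.sum()
    return PSFVolume(data=data, voxel=voxel)


@pytest.fixture(scope="session")
def gauss_psf() -> PSFVolume:
    return make_gaussian_psf()
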