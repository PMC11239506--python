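"""In-silico smFISH z-stack generator.

Ground truth: Gaussian blobs (one per transcript) of total intensity
``amplitude`` and sigma ``blob_sigma`` pixels, placed uniformly at random
sub-pixel positions and rasterized exactly by integrating the Gaussian over
each voxel (products of per-axis CDF differences), on a constant background.
Corruption emulates a widefield camera image: convolution with the
microscope PSF (the volume is padded with the background level first, as if
cut from a larger uniform specimen), a per-voxel Poisson draw, additive
Gaussian read noise, and clamping at zero.

Defaults follow the benchmark recipe: 255 x 255 x 40 voxels at 130 nm
isotropic, blob total intensity 10,000, sigma 0.7 px, background 1,000,
sensor noise sigma 10.  The signal-to-noise ratio is defined as the peak of
the convolved blob above background divided by the noise level at
background, sqrt(background + sensor_sigma^2); ``amplitude_for_snr`` maps a
target SNR to the blob amplitude under this definition.  All randomness
comes from a named, seeded generator (NumPy PCG64) so stacks reproduce
bit-for-bit across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import ndtr

from .deconv import VolumeImage
from .psf import PSFVolume

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "render_ground_truth",
    "corrupt",
    "amplitude_for_snr",
    "simulate_stack",
]

# dot centers stay this far from the borders so blob mass stays in frame
LATERAL_MARGIN_PX = 3.0
AXIAL_MARGIN_PX = 2.0
_BLOB_WINDOW = 6  # +-6 px window truncates < 1e-7 of blob mass at sigma 0.7


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic stack (shape is (nx, ny, nz))."""

    shape: tuple[int, int, int] = (255, 255, 40)
    voxel: float = 130.0  # nm, isotropic
    n_dots: int = 200
    amplitude: float = 10_000.0
    blob_sigma: float = 0.7  # pixels
    background: float = 1_000.0
    sensor_sigma: float = 10.0
    snr: float | None = None  # when set, overrides amplitude via amplitude_for_snr
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dots < 0 or self.blob_sigma <= 0:
            raise ValueError("n_dots must be >= 0 and blob_sigma > 0")
        if min(self.amplitude, self.background, self.sensor_sigma) < 0:
            raise ValueError("intensities and noise scales must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Clean pre-PSF image plus the true sub-pixel dot centers.

    ``positions`` columns are (x, y, z) in pixels, 0-based, voxel-center
    convention; ``image.data`` axis order is (z, y, x).
    """

    image: VolumeImage
    positions: np.ndarray


def _axis_mass(center: float, n: int, sigma: float) -> tuple[slice, np.ndarray]:
    """Pixel masses of a unit 1D Gaussian: CDF differences across voxel
    boundaries, on the in-bounds part of a +-window around the center."""
    a = max(0, int(round(center)) - _BLOB_WINDOW)
    b = min(n, int(round(center)) + _BLOB_WINDOW + 1)
    idx = np.arange(a, b)
    mass = ndtr((idx + 0.5 - center) / sigma) - ndtr((idx - 0.5 - center) / sigma)
    return slice(a, b), mass


def render_ground_truth(spec: SimulationSpec) -> GroundTruth:
    """Rasterize the stated number of randomly placed blobs plus background."""
    nx, ny, nz = spec.shape
    rng = np.random.default_rng(spec.seed)
    mx, mz = LATERAL_MARGIN_PX, AXIAL_MARGIN_PX
    pos = np.column_stack(
        [
            rng.uniform(mx, nx - 1 - mx, spec.n_dots),
            rng.uniform(mx, ny - 1 - mx, spec.n_dots),
            rng.uniform(mz, nz - 1 - mz, spec.n_dots),
        ]
    )
    img = np.zeros((nz, ny, nx), dtype=np.float64)
    for x, y, z in pos:
        sx, wx = _axis_mass(x, nx, spec.blob_sigma)
        sy, wy = _axis_mass(y, ny, spec.blob_sigma)
        sz, wz = _axis_mass(z, nz, spec.blob_sigma)
        img[sz, sy, sx] += spec.amplitude * (
            wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
        )
    img += spec.background
    vol = VolumeImage(img.astype(np.float32), voxel=(spec.voxel,) * 3)
    return GroundTruth(image=vol, positions=pos)


def corrupt(gt: GroundTruth, psf: PSFVolume, spec: SimulationSpec) -> VolumeImage:
    """Blur with the PSF and apply Poisson shot noise + Gaussian read noise.

    The clean image is padded with the constant background before the
    convolution (the field of view behaves like a crop from a larger
    uniform specimen), then cropped back to the original extents.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    half = tuple((s - 1) // 2 for s in psf.data.shape)
    padded = np.pad(
        gt.image.data.astype(np.float64),
        [(h, h) for h in half],
        mode="constant",
        constant_values=spec.background,
    )
    blurred = fftconvolve(padded, psf.data, mode="same")
    core = tuple(slice(h, h + s) for h, s in zip(half, gt.image.data.shape))
    blurred = np.maximum(blurred[core], 0.0)
    noisy = rng.poisson(blurred).astype(np.float64)
    if spec.sensor_sigma > 0:
        noisy += rng.normal(0.0, spec.sensor_sigma, noisy.shape)
    noisy = np.maximum(noisy, 0.0).astype(np.float32)
    return VolumeImage(noisy, voxel=gt.image.voxel)


def _unit_peak(spec: SimulationSpec, psf: PSFVolume) -> float:
    """Peak voxel value of one unit-amplitude centered blob after the PSF."""
    n = 2 * _BLOB_WINDOW + 1
    _, wx = _axis_mass(float(_BLOB_WINDOW), n, spec.blob_sigma)
    blob = wx[:, None, None] * wx[None, :, None] * wx[None, None, :]
    return float(fftconvolve(blob, psf.data, mode="full").max())


def amplitude_for_snr(snr: float, spec: SimulationSpec, psf: PSFVolume) -> float:
    """Blob amplitude so that (convolved peak above background)/noise = snr.

    Signal is the peak voxel of the PSF-convolved blob above the constant
    background; noise is the combined Poisson + Gaussian standard deviation
    at background level, sqrt(background + sensor_sigma^2).  The mapping is
    linear in the amplitude.  Note the unit-sum 3D widefield PSF spreads a
    dot's energy over the full axial range, so SNR-matched amplitudes are
    large multiples of the blob's in-focus ground-truth peak.
    """
    if snr < 0:
        raise ValueError("snr must be >= 0")
    noise = np.sqrt(spec.background + spec.sensor_sigma**2)
    return snr * noise / _unit_peak(spec, psf)


def simulate_stack(spec: SimulationSpec, psf: PSFVolume) -> tuple[GroundTruth, VolumeImage]:
    """Ground truth + corrupted stack; resolves ``spec.snr`` to an amplitude."""
    if spec.snr is not None:
        spec = replace(spec, amplitude=amplitude_for_snr(spec.snr, spec, psf), snr=None)
    gt = render_ground_truth(spec)
    return gt, corrupt(gt, psf, spec)
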