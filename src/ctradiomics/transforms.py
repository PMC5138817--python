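"""Derived images for texture analysis: 2D wavelet sub-bands and Gabor maps.

Both transforms operate slice-wise (in-plane) on the ROI bounding-box patch.
The wavelet transform is a one-level 2D DWT giving the four canonical bands
LL, LH, HL, HH; a 3D transform would give eight bands and is out of scope.

The Gabor bank uses complex kernels (Gaussian envelope times a complex
carrier) with the DC component subtracted, so filter responses are exactly
invariant to adding a constant offset to the image. Magnitude maps feed the
"MTR" (magnitude texture representation) statistics, phase maps the "PTR"
(phase texture representation) statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import convolve

__all__ = [
    "SubbandSet",
    "GaborResponse",
    "wavelet_decompose",
    "wavelet_reconstruct",
    "gabor_kernel",
    "gabor_bank",
    "default_orientations",
]

BAND_NAMES = ("LL", "LH", "HL", "HH")


@dataclass
class SubbandSet:
    """One-level 2D DWT coefficients per slice.

    ``bands[name]`` is a stack shaped (n_slices, ceil(ny/2), ceil(nx/2)) for
    each of LL, LH, HL, HH.
    """

    bands: dict[str, np.ndarray]
    wavelet: str = "haar"
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if set(self.bands) != set(BAND_NAMES):
            raise ValueError(f"bands must be exactly {BAND_NAMES}")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"band shapes differ: {shapes}")


@dataclass
class GaborResponse:
    """Complex Gabor filter response for one (scale, orientation)."""

    scale_index: int
    orientation_index: int
    magnitude: np.ndarray  # (n_slices, ny, nx), >= 0
    phase: np.ndarray  # (n_slices, ny, nx), in (-pi, pi]
    frequency: float
    theta: float


def wavelet_decompose(
    patch: np.ndarray, wavelet: str = "haar", mode: str = "symmetric"
) -> SubbandSet:
    """One-level 2D DWT applied to every slice of a 3D patch.

    Parameters
    ----------
    patch : ndarray (n_slices, ny, nx)
        ROI bounding-box intensities. In-plane size must be >= 2x2.
    wavelet : str
        PyWavelets wavelet name; the default Haar is orthonormal, so the sum
        of squared coefficients over the four bands equals the sum of squared
        pixels for even-sized slices.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim == 2:
        patch = patch[None]
    if patch.ndim != 3:
        raise ValueError(f"patch must be 2D or 3D, got shape {patch.shape}")
    if patch.shape[1] < 2 or patch.shape[2] < 2:
        raise ValueError(
            f"ROI bounding box must be at least 2x2 in-plane, got "
            f"{patch.shape[1]}x{patch.shape[2]}"
        )
    lls, lhs, hls, hhs = [], [], [], []
    for sl in patch:
        ll, (lh, hl, hh) = pywt.dwt2(sl, wavelet, mode=mode)
        lls.append(ll)
        lhs.append(lh)
        hls.append(hl)
        hhs.append(hh)
    bands = {
        "LL": np.stack(lls),
        "LH": np.stack(lhs),
        "HL": np.stack(hls),
        "HH": np.stack(hhs),
    }
    return SubbandSet(bands, wavelet=wavelet, mode=mode)


def wavelet_reconstruct(subbands: SubbandSet, out_shape=None) -> np.ndarray:
    """Inverse of :func:`wavelet_decompose` (perfect reconstruction)."""
    slices = []
    n = subbands.bands["LL"].shape[0]
    for i in range(n):
        rec = pywt.idwt2(
            (
                subbands.bands["LL"][i],
                (
                    subbands.bands["LH"][i],
                    subbands.bands["HL"][i],
                    subbands.bands["HH"][i],
                ),
            ),
            subbands.wavelet,
            mode=subbands.mode,
        )
        slices.append(rec)
    out = np.stack(slices)
    if out_shape is not None:
        out = out[:, : out_shape[1], : out_shape[2]]
    return out


def default_orientations(n: int = 30) -> np.ndarray:
    """Evenly spaced orientations over [0, pi)."""
    return np.arange(n) * np.pi / n


def gabor_kernel(
    frequency: float, theta: float, bandwidth: float = 1.0
) -> np.ndarray:
    """Complex 2D Gabor kernel with exactly zero DC response.

    Gaussian envelope SD follows the standard one-octave-bandwidth relation
    sigma = (1/pi) * sqrt(ln 2 / 2) * (2^b + 1)/(2^b - 1) / frequency.
    The kernel mean is subtracted so convolution with a constant image is
    exactly zero.
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    if frequency > 0.5:
        raise ValueError(
            f"frequency {frequency} cycles/voxel exceeds Nyquist (0.5): "
            "wavelength shorter than 2 voxels would alias"
        )
    b = bandwidth
    sigma = (1.0 / np.pi) * np.sqrt(np.log(2) / 2.0) * (2.0**b + 1) / (2.0**b - 1)
    sigma /= frequency
    half = int(np.ceil(3.5 * sigma))
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    rot_x = x * np.cos(theta) + y * np.sin(theta)
    envelope = np.exp(-(x**2 + y**2) / (2 * sigma**2))
    carrier = np.exp(2j * np.pi * frequency * rot_x)
    kern = envelope * carrier
    kern /= np.abs(kern).sum()
    kern -= kern.mean()  # exact zero-DC: offset invariance of |response|
    return kern


def gabor_bank(
    patch: np.ndarray,
    frequencies=(0.15,),
    orientations=None,
    bandwidth: float = 1.0,
) -> list[GaborResponse]:
    """Filter every slice of a patch with a bank of complex Gabor kernels.

    Parameters
    ----------
    patch : ndarray (n_slices, ny, nx)
    frequencies : sequence of float
        Center frequencies in cycles/voxel; scale index s starts at 1.
    orientations : sequence of float, optional
        Orientations in radians; default 30 evenly spaced over [0, pi),
        orientation index o starting at 0.

    Returns one :class:`GaborResponse` per (scale, orientation), with
    magnitude and phase maps per slice. Boundary handling is symmetric
    (mirror) padding.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim == 2:
        patch = patch[None]
    if orientations is None:
        orientations = default_orientations()
    orientations = np.asarray(orientations, dtype=float)
    responses: list[GaborResponse] = []
    for si, f in enumerate(frequencies, start=1):
        for oi, theta in enumerate(orientations):
            kern = gabor_kernel(f, theta, bandwidth)
            mags, phases = [], []
            for sl in patch:
                re = convolve(sl, kern.real, mode="mirror")
                im = convolve(sl, kern.imag, mode="mirror")
                resp = re + 1j * im
                mags.append(np.abs(resp))
                phases.append(np.angle(resp))
            responses.append(
                GaborResponse(
                    scale_index=si,
                    orientation_index=oi,
                    magnitude=np.stack(mags),
                    phase=np.stack(phases),
                    frequency=float(f),
                    theta=float(theta),
                )
            )
    return responses
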