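"""Fourier conventions and rigid transforms for Cartesian 2-D k-space.

Conventions used throughout the package:

* k-space is always DC-centred (``fftshift`` layout) and produced with the
  orthonormal FFT, so Parseval's identity holds with unit constant:
  ``sum(|image|**2) == sum(|kspace|**2)``.
* The phase-encoding (PE) direction is axis 0 (rows = ky).  Inter-shot
  rigid motion corrupts whole PE lines, which is why corruption masks in
  this package are per-row vectors.
* Rigid in-plane motion is parameterised as ``(theta_deg, tx_mm, ty_mm)``:
  a translation applied first, then a rotation about the geometric image
  centre — the k-space version is the conjugation of that spatial map by
  the Fourier transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

PE_AXIS = 0  # rows are phase-encoding lines, globally fixed

__all__ = [
    "PE_AXIS", "ImageSlice", "KSpaceSlice",
    "to_kspace", "from_kspace", "rigid_transform_image", "kspace_rigid",
]


@dataclass
class ImageSlice:
    """A 2-D real magnitude image in the spatial domain.

    Parameters
    ----------
    pixels : ndarray
        Real H x W array.  Loaders normalise to [0, 1]; motion-corrupted
        magnitudes may slightly overshoot.
    pixel_spacing : float
        Millimetres per pixel (isotropic).  Translations given in mm are
        converted to pixels through this value.
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D slice, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < 8 or w < 8:
            raise ValueError(f"slice too small ({h}x{w}); need at least 8x8")
        if not np.isfinite(self.pixels).all():
            raise ValueError("non-finite values in image slice")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class KSpaceSlice:
    """DC-centred complex Fourier coefficients of one slice."""

    coeffs: np.ndarray
    pixel_spacing: float = 1.0
    pe_axis: int = field(default=PE_AXIS)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.complex128)
        if self.coeffs.ndim != 2:
            raise ValueError(f"expected 2-D k-space, got shape {self.coeffs.shape}")
        if self.pe_axis != PE_AXIS:
            raise ValueError("phase-encoding axis is fixed to axis 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.coeffs.shape


def to_kspace(img: ImageSlice) -> KSpaceSlice:
    """Forward 2-D Fourier transform, DC-centred, orthonormal."""
    if not np.isfinite(img.pixels).all():
        raise ValueError("to_kspace: non-finite values in input slice")
    k = np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img.pixels), norm="ortho"))
    return KSpaceSlice(k, pixel_spacing=img.pixel_spacing)


def from_kspace(ks: KSpaceSlice) -> ImageSlice:
    """Centred inverse transform back to a real magnitude image.

    Spectra of real images are conjugate-symmetric and invert to a real
    image (the tiny imaginary residue is dropped).  Motion-corrupted
    spectra lose that symmetry; their inverse is genuinely complex and the
    magnitude image is returned, matching how MR magnitude images are
    displayed.
    """
    x = np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ks.coeffs), norm="ortho"))
    if np.abs(x.imag).max() > 1e-6:
        pix = np.abs(x)
    else:
        pix = x.real
    return ImageSlice(pix, pixel_spacing=ks.pixel_spacing)


def _affine_params(shape: tuple[int, int], theta_deg: float,
                   tx_mm: float, ty_mm: float, pixel_spacing: float):
    """Inverse-map matrix/offset for translate-then-rotate about the centre."""
    h, w = shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])  # (row, col)
    t = np.array([ty_mm / pixel_spacing, tx_mm / pixel_spacing])
    th = np.deg2rad(theta_deg)
    # rotation in array (row, col) coordinates; inverse map for ndimage
    rinv = np.array([[np.cos(th), np.sin(th)],
                     [-np.sin(th), np.cos(th)]])
    offset = c - rinv @ c - t
    return rinv, offset


def rigid_transform_image(img: ImageSlice, theta_deg: float,
                          tx_mm: float, ty_mm: float) -> ImageSlice:
    """Translate by (tx, ty) mm then rotate by theta about the image centre.

    Bilinear interpolation; samples falling outside the grid are zero.
    The identity parameters return the input bit-exactly.
    """
    if abs(theta_deg) > 180:
        raise ValueError("rotation angle must satisfy |theta| <= 180 degrees")
    if theta_deg == 0.0 and tx_mm == 0.0 and ty_mm == 0.0:
        return ImageSlice(img.pixels.copy(), pixel_spacing=img.pixel_spacing)
    rinv, offset = _affine_params(img.shape, theta_deg, tx_mm, ty_mm,
                                  img.pixel_spacing)
    out = ndimage.affine_transform(img.pixels, rinv, offset=offset,
                                   order=1, mode="constant", cval=0.0)
    return ImageSlice(out, pixel_spacing=img.pixel_spacing)


def kspace_rigid(ks: KSpaceSlice, theta_deg: float,
                 tx_mm: float, ty_mm: float) -> KSpaceSlice:
    """Rigid motion applied in k-space: inverse FFT, translate, rotate, FFT.

    For the conjugate-symmetric spectrum of a real image this equals
    ``to_kspace(rigid_transform_image(from_kspace(ks), ...))``; complex
    intermediate images are handled by transforming real and imaginary
    parts separately (the spatial map is real-linear).
    """
    if theta_deg == 0.0 and tx_mm == 0.0 and ty_mm == 0.0:
        return KSpaceSlice(ks.coeffs.copy(), pixel_spacing=ks.pixel_spacing)
    x = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ks.coeffs), norm="ortho"))
    rinv, offset = _affine_params(ks.shape, theta_deg, tx_mm, ty_mm,
                                  ks.pixel_spacing)
    xr = ndimage.affine_transform(x.real, rinv, offset=offset,
                                  order=1, mode="constant", cval=0.0)
    xi = ndimage.affine_transform(x.imag, rinv, offset=offset,
                                  order=1, mode="constant", cval=0.0)
    k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(xr + 1j * xi),
                                    norm="ortho"))
    return KSpaceSlice(k, pixel_spacing=ks.pixel_spacing)
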