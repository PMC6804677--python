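"""Scalar-diffraction engine for lensless in-line holography.

Free-space propagation uses the angular spectrum method: the field's 2D
spatial-frequency spectrum is multiplied by the exact transfer function

    H(f_x, f_y; z) = exp( i 2*pi/lambda * z * sqrt(1 - (lambda f_x)^2 - (lambda f_y)^2) )

with evanescent components ((lambda f_x)^2 + (lambda f_y)^2 > 1) set to
zero.  On the unpadded (circular) grid this operator is unitary and exactly
invertible by negating the distance; zero-padding is available to suppress
wrap-around for fields that spread during propagation.

Sign convention: positive ``distance`` propagates the field along the
illumination direction (source -> sensor); back-propagation toward the
object uses a negative distance.

Reconstruction of a recorded hologram frame A_i over a depth grid z_j is
the composition  B_i(z_j) = HP[ P(A_i, -z_j) ]  of back-propagation and a
radially symmetric Gaussian high-pass filter that removes the DC term and
low-frequency background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft

__all__ = [
    "ComplexField",
    "DepthGrid",
    "FilterSpec",
    "angular_spectrum_propagate",
    "high_pass_filter",
    "filtered_backpropagate",
]


@dataclass(frozen=True)
class ComplexField:
    """A monochromatic scalar field sampled on a regular 2D grid.

    Parameters
    ----------
    values : ndarray
        2D complex array; rows are y, columns are x.
    pixel_pitch : float
        Sample spacing in micrometres.
    wavelength : float
        Illumination wavelength in micrometres.
    """

    values: np.ndarray
    pixel_pitch: float
    wavelength: float

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"field must be 2D, got shape {v.shape}")
        if not np.iscomplexobj(v):
            v = v.astype(np.complex128 if v.dtype.itemsize >= 8 else np.complex64)
        if not np.all(np.isfinite(v)):
            raise ValueError("field values must be finite")
        object.__setattr__(self, "values", v)
        if not (self.pixel_pitch > 0 and self.wavelength > 0):
            raise ValueError("pixel_pitch and wavelength must be positive")
        if self.wavelength >= 2 * self.pixel_pitch:
            warnings.warn(
                "wavelength >= 2 * pixel_pitch: the propagating band is "
                "undersampled (aliasing possible)",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2


@dataclass(frozen=True)
class DepthGrid:
    """Ordered axial search positions z_j (micrometres) for reconstruction."""

    z_values: np.ndarray
    step: float

    def __post_init__(self):
        z = np.asarray(self.z_values, dtype=float)
        if z.ndim != 1 or z.size == 0:
            raise ValueError("z_values must be a non-empty 1D array")
        if not np.all(np.diff(z) > 0):
            raise ValueError("z_values must be strictly increasing")
        object.__setattr__(self, "z_values", z)

    @classmethod
    def regular(cls, z_min: float = 800.0, z_max: float = 5000.0, step: float = 100.0) -> "DepthGrid":
        """Regular grid covering [z_min, z_max]; defaults give the 43-plane
        screening grid (800 to 5000 um in 100 um steps)."""
        n = int(round((z_max - z_min) / step)) + 1
        return cls(z_values=z_min + step * np.arange(n), step=step)

    def __len__(self) -> int:
        return len(self.z_values)


@dataclass(frozen=True)
class FilterSpec:
    """Spatial high-pass filter applied to each reconstructed plane.

    ``gaussian_highpass`` has transfer function 1 - exp(-f^2 / (2 sigma_f^2))
    with f the radial spatial frequency in cycles/um: exactly zero at DC,
    approaching one well above ``cutoff_frequency`` (= sigma_f).
    """

    kind: str = "gaussian_highpass"
    cutoff_frequency: float = 0.01  # sigma_f, cycles/um

    def __post_init__(self):
        if self.kind != "gaussian_highpass":
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.cutoff_frequency < 0:
            raise ValueError("cutoff_frequency must be >= 0")

    def transfer(self, f_radial: np.ndarray) -> np.ndarray:
        """Evaluate the transfer function at radial frequencies (cycles/um)."""
        f = np.asarray(f_radial, dtype=float)
        if self.cutoff_frequency == 0:
            t = np.ones_like(f)
            t[f == 0] = 0.0
            return t
        return 1.0 - np.exp(-(f**2) / (2.0 * self.cutoff_frequency**2))


def _pad(values: np.ndarray, pad_factor: int) -> tuple[np.ndarray, tuple[slice, slice]]:
    if pad_factor <= 1:
        return values, (slice(None), slice(None))
    ny, nx = values.shape
    py, px = ny * (pad_factor - 1), nx * (pad_factor - 1)
    top, left = py // 2, px // 2
    out = np.zeros((ny + py, nx + px), dtype=values.dtype)
    out[top : top + ny, left : left + nx] = values
    return out, (slice(top, top + ny), slice(left, left + nx))


def _as_transfer(shape: tuple[int, int], pitch: float, wavelength: float, distance: float, dtype) -> np.ndarray:
    """Angular-spectrum transfer function on an FFT grid, evanescent zeroed."""
    fy = sfft.fftfreq(shape[0], d=pitch)
    fx = sfft.fftfreq(shape[1], d=pitch)
    lf2 = (wavelength * fy[:, None]) ** 2 + (wavelength * fx[None, :]) ** 2
    propagating = lf2 <= 1.0
    kz = np.zeros(shape)
    kz[propagating] = (2.0 * np.pi / wavelength) * np.sqrt(1.0 - lf2[propagating])
    H = np.exp(1j * distance * kz)
    H[~propagating] = 0.0
    return H.astype(dtype)


def angular_spectrum_propagate(
    field: ComplexField, distance: float, pad_factor: int = 1
) -> ComplexField:
    """Propagate a field by ``distance`` micrometres (signed).

    With ``pad_factor=1`` the operator acts on the circular grid, conserves
    energy for propagating components, and ``distance -> -distance`` is its
    exact inverse.  ``pad_factor>1`` zero-pads before the FFT to suppress
    wrap-around and crops back to the input grid.
    """
    if not np.isfinite(distance):
        raise ValueError("distance must be finite")
    v = field.values
    ctype = np.complex64 if v.dtype == np.complex64 else np.complex128
    padded, window = _pad(v.astype(ctype, copy=False), pad_factor)
    H = _as_transfer(padded.shape, field.pixel_pitch, field.wavelength, distance, ctype)
    out = sfft.ifft2(sfft.fft2(padded) * H)[window]
    return replace(field, values=out)


def high_pass_filter(field: ComplexField, spec: FilterSpec | None = None, pad_factor: int = 1) -> ComplexField:
    """Multiply the field's spectrum by the high-pass transfer function.

    The zero-frequency (mean) component is removed exactly.
    """
    spec = spec or FilterSpec()
    v = field.values
    ctype = np.complex64 if v.dtype == np.complex64 else np.complex128
    padded, window = _pad(v.astype(ctype, copy=False), pad_factor)
    fy = sfft.fftfreq(padded.shape[0], d=field.pixel_pitch)
    fx = sfft.fftfreq(padded.shape[1], d=field.pixel_pitch)
    f = np.hypot(fy[:, None], fx[None, :])
    T = spec.transfer(f).astype(np.float32 if ctype == np.complex64 else np.float64)
    spectrum = sfft.fft2(padded)
    spectrum *= T
    spectrum[0, 0] = 0.0  # DC removed exactly
    out = sfft.ifft2(spectrum)[window]
    return replace(field, values=out)


def filtered_backpropagate(
    frame: ComplexField,
    grid: DepthGrid,
    spec: FilterSpec | None = None,
    pad_factor: int = 2,
    sqrt_intensity: bool = False,
) -> np.ndarray:
    """Reconstruct a hologram frame over a depth grid.

    Returns a complex array of shape ``(len(grid), H, W)`` whose plane j is
    exactly ``high_pass_filter(angular_spectrum_propagate(frame, -z_j))``.
    The recorded intensity frame is used directly as a real-valued field
    (``sqrt_intensity=True`` takes its square root first).  Frames are
    mean-subtracted before zero-padding so the pad discontinuity does not
    ring through the reconstruction; the mean is part of the DC term the
    high-pass filter removes anyway.
    """
    if len(grid) == 0:
        raise ValueError("depth grid is empty")
    spec = spec or FilterSpec()
    v = frame.values
    if sqrt_intensity:
        v = np.sqrt(np.clip(v.real, 0, None)).astype(v.real.dtype)
    ctype = np.complex64 if v.dtype in (np.complex64, np.float32) else np.complex128
    v = v.astype(ctype) - v.mean()
    base = replace(frame, values=v)
    out = np.empty((len(grid),) + frame.shape, dtype=ctype)
    # share the forward FFT of the padded frame across depths: identical
    # floating-point operations to calling angular_spectrum_propagate per z
    padded, window = _pad(v, pad_factor)
    F = sfft.fft2(padded)
    for j, z in enumerate(grid.z_values):
        H = _as_transfer(padded.shape, frame.pixel_pitch, frame.wavelength, -float(z), ctype)
        plane = sfft.ifft2(F * H)[window]
        out[j] = high_pass_filter(replace(base, values=plane), spec, pad_factor=pad_factor).values
    return out
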