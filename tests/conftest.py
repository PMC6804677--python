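import numpy as np
import pytest

from holocyte.optics import ComplexField

PITCH = 1.67  # um
WAVELENGTH = 0.65  # um


def band_limited_field(n: int = 64, k: int = 8, seed: int = 0,
                       pitch: float = PITCH) -> ComplexField:
    """Random field whose spectrum occupies only the lowest k x k modes."""
    rng = np.random.default_rng(seed)
    spec = np.zeros((n, n), dtype=complex)
    spec[:k, :k] = rng.normal(size=(k, k)) + 1j * rng.normal(size=(k, k))
    values = np.fft.ifft2(spec)
    return ComplexField(values, pixel_pitch=pitch, wavelength=WAVELENGTH)


def fourier_shift(img: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Circularly shift image content by (+dx, +dy) px via the FFT."""
    F = np.fft.fft2(img)
    fy = np.fft.fftfreq(img.shape[0])[:, None]
    fx = np.fft.fftfreq(img.shape[1])[None, :]
    return np.real(np.fft.ifft2(F * np.exp(-2j * np.pi * (fx * dx + fy * dy))))


@pytest.fixture(scope="session")
def speckle_image():
    """A band-limited speckle-like test image for registration tests."""
    rng = np.random.default_rng(42)
    spec = np.zeros((128, 128), dtype=complex)
    spec[:16, :16] = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
    return np.abs(np.fft.ifft2(spec)) * 100 + 50
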