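"""Centred FFT helpers.

All spectra in this package live on grids whose zero frequency sits at
index ``N//2`` and whose real-space origin sits at the array centre, so a
phantom centred in its grid has a smooth (ramp-free) spectrum.  Frequency
bin ``i`` maps to ``(i - N//2) * dk`` with ``dk = 2π / (N * dx)`` rad/μm.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ft2c",
    "ift2c",
    "ft3c",
    "ift3c",
    "freq_axis",
    "fourier_upsample",
]


def ft2c(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a, axes=(-2, -1))),
                           axes=(-2, -1))


def ift2c(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a, axes=(-2, -1))),
                           axes=(-2, -1))


def ft3c(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a)))


def ift3c(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(a)))


def freq_axis(n: int, dx: float) -> np.ndarray:
    """Angular frequency samples (rad/μm) for a centred n-point grid."""
    return (np.arange(n) - n // 2) * (2.0 * np.pi / (n * dx))


def fourier_upsample(a: np.ndarray, factor: int) -> np.ndarray:
    """Exact band-limited upsampling by spectrum zero-padding.

    Preserves amplitude; the output grid spans the same field of view at
    ``factor``× finer sampling.  Exactly invertible by cropping the central
    spectral block.
    """
    if factor == 1:
        return a.copy()
    ny, nx = a.shape
    my, mx = ny * factor, nx * factor
    spec = ft2c(a)
    pad = np.zeros((my, mx), dtype=complex)
    y0, x0 = my // 2 - ny // 2, mx // 2 - nx // 2
    pad[y0:y0 + ny, x0:x0 + nx] = spec
    return ift2c(pad) * factor ** 2
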