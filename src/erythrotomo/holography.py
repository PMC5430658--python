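"""Off-axis field retrieval: sideband demodulation, unwrapping, flattening.

The retrieval is the standard Fourier-space demodulation of an off-axis
hologram: locate the +1-order sideband, crop a disk around it, recentre it
to zero frequency and inverse-transform.  Because interferograms are
synthesized on an upsampled grid whose spectral bins coincide with the
source field's bins, the crop demodulates back onto the original field grid
and the loop is exact for band-limited, noise-free fields.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.restoration import unwrap_phase as _sk_unwrap

from .containers import ComplexField2D, Interferogram
from .fourier import ft2c, ift2c

__all__ = [
    "RetrievalConfig",
    "retrieve_field",
    "unwrap_phase",
    "normalize_background",
    "NoSidebandError",
]


class NoSidebandError(ValueError):
    """Raised when the hologram spectrum has no detectable carrier peak."""


@dataclass
class RetrievalConfig:
    """Sideband-demodulation parameters.

    ``sideband_radius`` (cycles/μm) defaults to half the carrier distance,
    shrunk if necessary so the crop circle stays clear of the DC
    autocorrelation term (radius 2× the sample band limit) — that keeps the
    retrieval exact whenever the geometry permits.
    """

    sideband_radius: Optional[float] = None
    window: str = "hard"  # "hard" | "cosine" edge of the crop disk
    edge_width: float = 0.1  # fraction of the radius, cosine window only
    proceed_on_overlap: bool = False

    def resolve_radius(self, carrier_mag: float,
                       band_limit: Optional[float]) -> float:
        r = self.sideband_radius
        if r is None:
            r = 0.5 * carrier_mag
            if band_limit is not None:
                r = min(r, carrier_mag - 2.0 * band_limit)
                r = max(r, min(band_limit, 0.5 * carrier_mag))
        return r


def _detect_carrier(spec: np.ndarray, df: float) -> np.ndarray:
    """Brightest non-DC peak, restricted to the fy > 0 (or fy = 0, fx > 0)
    half-plane to break the conjugate-order ambiguity."""
    m = spec.shape[0]
    c = m // 2
    mag = np.abs(spec).copy()
    guard = max(2, m // 64)
    mag[c - guard:c + guard + 1, c - guard:c + guard + 1] = 0.0
    half = np.zeros_like(mag, dtype=bool)
    half[c + 1:, :] = True
    half[c, c + 1:] = True
    mag[~half] = 0.0
    iy, ix = np.unravel_index(np.argmax(mag), mag.shape)
    dc_mag = np.abs(spec[c, c])
    if mag[iy, ix] < 1e-6 * max(dc_mag, 1e-30):
        raise NoSidebandError("no detectable sideband in the spectrum")
    return np.array([(ix - c) * df, (iy - c) * df])


def retrieve_field(ig: Interferogram, cfg: Optional[RetrievalConfig] = None
                   ) -> ComplexField2D:
    """Demodulate an off-axis interferogram into a complex field."""
    cfg = cfg or RetrievalConfig()
    I = ig.intensity
    m = I.shape[0]
    if I.shape[0] != I.shape[1]:
        raise ValueError("expected a square interferogram")
    fov = m * ig.pixel_size
    df = 1.0 / fov
    spec = ft2c(I)

    if ig.carrier is not None and np.all(np.isfinite(ig.carrier)) \
            and np.linalg.norm(ig.carrier) > 0:
        fc = np.asarray(ig.carrier, dtype=float)
    else:
        fc = _detect_carrier(spec, df)

    if ig.source_shape is not None:
        n = int(ig.source_shape[0])
    else:
        n = m

    radius = cfg.resolve_radius(float(np.linalg.norm(fc)), ig.band_limit)
    if ig.band_limit is not None and \
            radius + 2.0 * ig.band_limit > np.linalg.norm(fc) + 1e-9:
        msg = ("sideband crop overlaps the DC autocorrelation term; "
               "retrieved field may be contaminated")
        if cfg.proceed_on_overlap:
            warnings.warn(msg)
        else:
            warnings.warn(msg + " (proceeding; set sideband_radius to "
                          "silence)")

    cy = m // 2 + int(round(fc[1] / df))
    cx = m // 2 + int(round(fc[0] / df))
    y0, x0 = cy - n // 2, cx - n // 2
    if y0 < 0 or x0 < 0 or y0 + n > m or x0 + n > m:
        raise NoSidebandError("carrier too close to the spectrum edge")
    block = spec[y0:y0 + n, x0:x0 + n].copy()

    fy = (np.arange(n) - n // 2) * df
    r2 = fy[:, None] ** 2 + fy[None, :] ** 2
    if cfg.window == "hard":
        w = (r2 <= radius ** 2).astype(float)
    elif cfg.window == "cosine":
        r = np.sqrt(r2)
        flat = radius * (1.0 - cfg.edge_width)
        w = 0.5 * (1.0 + np.cos(np.pi * np.clip(
            (r - flat) / max(radius - flat, 1e-12), 0.0, 1.0)))
        w[r > radius] = 0.0
    else:
        raise ValueError(f"unknown window {cfg.window!r}")
    block *= w

    factor = m / n
    u = ift2c(block) / factor ** 2
    return ComplexField2D(
        field=u, pixel_size=ig.pixel_size * factor, k_in=ig.k_in,
        wavelength_nm=ig.wavelength_nm, n_m=ig.n_m)


def unwrap_phase(wrapped: np.ndarray, return_residues: bool = False):
    """Reliability-sorted 2-D phase unwrapping.

    The output equals the input modulo 2π and is spatially continuous along
    the unwrapping path.  Optionally also returns the number of phase
    residues (a diagnostic for noisy inputs; 0 means a consistent field).
    """
    wrapped = np.asarray(wrapped, dtype=float)
    out = np.asarray(_sk_unwrap(wrapped))
    if not return_residues:
        return out
    return out, count_residues(wrapped)


def count_residues(wrapped: np.ndarray) -> int:
    """Number of 2×2 plaquettes whose wrapped phase circulation is ±2π."""

    def wrap(a):
        return (a + np.pi) % (2.0 * np.pi) - np.pi

    d1 = wrap(np.diff(wrapped, axis=1))[:-1, :]
    d2 = wrap(np.diff(wrapped, axis=0))[:, 1:]
    d3 = -wrap(np.diff(wrapped, axis=1))[1:, :]
    d4 = -wrap(np.diff(wrapped, axis=0))[:, :-1]
    loop = d1 + d2 + d3 + d4
    return int(np.sum(np.abs(loop) > math.pi))


def _border_mask(shape: tuple, frac: float = 0.125) -> np.ndarray:
    ny, nx = shape
    wy, wx = max(1, int(ny * frac)), max(1, int(nx * frac))
    m = np.zeros(shape, dtype=bool)
    m[:wy, :] = m[-wy:, :] = True
    m[:, :wx] = m[:, -wx:] = True
    return m


def normalize_background(field: ComplexField2D,
                         background: Optional[np.ndarray] = None,
                         reference: Optional[ComplexField2D] = None
                         ) -> ComplexField2D:
    """Remove residual background tilt and piston from the phase.

    A plane is least-squares fitted to the unwrapped phase over the
    background region (a border frame by default, or an explicit boolean
    mask) and subtracted, leaving zero mean background phase.  If a blank
    ``reference`` field is supplied the field is divided by it first.
    """
    u = field.field
    if reference is not None:
        u = u / np.where(np.abs(reference.field) > 0, reference.field, 1.0)
    phase = unwrap_phase(np.angle(u))
    bg = background if background is not None else _border_mask(u.shape)
    if not np.any(bg):
        raise ValueError("no background pixels to fit")
    ny, nx = u.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([xx[bg], yy[bg], np.ones(int(bg.sum()))])
    coef, *_ = np.linalg.lstsq(A, phase[bg], rcond=None)
    plane = coef[0] * xx + coef[1] * yy + coef[2]
    out = np.abs(u) * np.exp(1j * (phase - plane))
    return ComplexField2D(
        field=out, pixel_size=field.pixel_size, k_in=field.k_in,
        wavelength_nm=field.wavelength_nm, n_m=field.n_m)
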