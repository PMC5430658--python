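"""3-D refractive-index reconstruction by the Fourier diffraction theorem.

Each angled-illumination field contributes its 2-D Rytov-phase spectrum on
an Ewald hemisphere translated by −k_in in the object's 3-D frequency
space.  With the scattering potential f(r) = k0²(n² − n_m²) and the
first-Rytov field u_R = U_in · ln(U/U_in), the theorem reads

    f̂(k_⊥ − k_in,⊥, k_z − k_in,z) = (2 k_z / i) · û_R(k_⊥),
    k_z = sqrt(k_m² − |k_⊥|²),

which is inverted by a 3-D inverse FFT after coverage-count averaging of
overlapping samples.  The finite numerical apertures leave a conical region
of frequency space unsampled (the "missing cone"), producing axial
elongation and underestimated contrast; an iterative non-negativity
projection (POCS: clamp Δn < 0 in real space, restore measured samples in
Fourier space) fills it in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .containers import ComplexField2D, RIVolume
from .fourier import freq_axis, ft2c, ft3c, ift3c
from .holography import unwrap_phase

__all__ = [
    "FourierVolume",
    "ReconConfig",
    "map_ewald",
    "invert",
    "regularize_nonneg",
    "reconstruct",
]


@dataclass
class FourierVolume:
    """Coverage-averaged scattering-potential spectrum.

    ``spectrum`` holds the running *sum* of mapped samples divided through
    by ``coverage`` on access; zero wherever no angle contributed.
    """

    spectrum: np.ndarray  # complex, (n, n, n), summed samples
    coverage: np.ndarray  # int, same shape
    dk: float  # rad/μm
    voxel_size: float  # μm
    n_m: float
    wavelength_nm: float

    @property
    def averaged(self) -> np.ndarray:
        out = np.zeros_like(self.spectrum)
        np.divide(self.spectrum, self.coverage, out=out,
                  where=self.coverage > 0)
        return out

    @property
    def mask(self) -> np.ndarray:
        return self.coverage > 0


@dataclass
class ReconConfig:
    """Inversion and missing-cone regularization parameters.

    ``relaxation`` mixes the measured Fourier samples back in (1.0 restores
    them exactly); ``overrelax`` is the step length β of the alternating
    projection update f ← f + β(P(f) − f).  β = 1 is the plain POCS
    iteration with its monotone residual guarantee; β up to ~1.9 converges
    roughly three times faster on smooth phantoms and is what the pipeline
    profile uses.
    """

    use_rytov: bool = True  # False → first-Born (no log)
    iterations: int = 100
    relaxation: float = 1.0
    overrelax: float = 1.0
    support_constraint: bool = False
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not 0.0 < self.relaxation <= 1.0:
            raise ValueError("relaxation must lie in (0, 1]")
        if not 0.0 < self.overrelax < 2.0:
            raise ValueError("overrelax must lie in (0, 2)")


def map_ewald(fields: Sequence[ComplexField2D], cfg,
              recon_size: Optional[int] = None) -> FourierVolume:
    """Assemble the 3-D spectrum from a multi-angle field set.

    ``cfg`` is the :class:`~erythrotomo.optics_forward.OpticalConfig` that
    produced the fields (for the detection band limit).  The reconstruction
    grid is cubic with the detector's pixel pitch.
    """
    if not fields:
        raise ValueError("need at least one field")
    n = recon_size or fields[0].field.shape[0]
    dv = fields[0].pixel_size
    km = 2.0 * math.pi * fields[0].n_m / (fields[0].wavelength_nm * 1e-3)
    k_det = 2.0 * math.pi * cfg.band_limit
    dk = 2.0 * math.pi / (n * dv)

    spectrum = np.zeros((n, n, n), dtype=complex)
    coverage = np.zeros((n, n, n), dtype=np.int64)
    q = freq_axis(n, dv)

    for fld in fields:
        if fld.k_in is None or fld.k_in.shape != (3,):
            raise ValueError("field is missing its illumination wavevector")
        u = fld.field
        if u.shape[0] != n or u.shape[0] != u.shape[1]:
            raise ValueError("all fields must be square and equally sized")
        amp = np.abs(u)
        if np.any(amp <= 0):
            raise ValueError(
                "zero-amplitude pixels: the Rytov logarithm diverges")
        psi = np.log(amp) + 1j * unwrap_phase(np.angle(u))
        psi_hat = ft2c(psi) * dv ** 2

        kx = q[None, :] + fld.k_in[0]
        ky = q[:, None] + fld.k_in[1]
        k_perp2 = kx ** 2 + ky ** 2
        band = k_perp2 <= min(k_det, 0.999 * km) ** 2
        kz = np.sqrt(np.clip(km ** 2 - k_perp2, 0.0, None))

        iy, ix = np.nonzero(band)
        kzv = kz[iy, ix]
        vals = (2.0 * kzv / 1j) * psi_hat[iy, ix]
        gx = ix  # Kx = q[ix] exactly on-grid
        gy = iy
        gz = np.rint((kzv - fld.k_in[2]) / dk).astype(int) + n // 2
        ok = (gz >= 0) & (gz < n)
        np.add.at(spectrum, (gz[ok], gy[ok], gx[ok]), vals[ok])
        np.add.at(coverage, (gz[ok], gy[ok], gx[ok]), 1)
        # the potential is real, so f̂(−K) = conj(f̂(K)): deposit the
        # Hermitian partner as well (symmetrises coverage, keeps the
        # inverse transform real)
        hx, hy = n - gx, n - gy
        hz = n - gz
        ok2 = (hz >= 0) & (hz < n) & (hx < n) & (hy < n)
        np.add.at(spectrum, (hz[ok2], hy[ok2], hx[ok2]), np.conj(vals[ok2]))
        np.add.at(coverage, (hz[ok2], hy[ok2], hx[ok2]), 1)

    return FourierVolume(spectrum=spectrum, coverage=coverage, dk=dk,
                         voxel_size=dv, n_m=fields[0].n_m,
                         wavelength_nm=fields[0].wavelength_nm)


def _potential_to_ri(f: np.ndarray, n_m: float, k0: float) -> np.ndarray:
    n2 = np.clip(n_m ** 2 + f / k0 ** 2, 0.0, None)
    return np.sqrt(n2)


def invert(fv: FourierVolume, cfg: Optional[ReconConfig] = None) -> RIVolume:
    """Direct (unregularized) inversion of the assembled spectrum."""
    if not fv.mask.any():
        raise ValueError("empty coverage: nothing to invert")
    dv = fv.voxel_size
    k0 = 2.0 * math.pi / (fv.wavelength_nm * 1e-3)
    f = np.real(ift3c(fv.averaged)) / dv ** 3
    return RIVolume(data=_potential_to_ri(f, fv.n_m, k0), voxel_size=dv,
                    n_m=fv.n_m, wavelength_nm=fv.wavelength_nm)


def regularize_nonneg(vol: RIVolume, fv: FourierVolume,
                      cfg: Optional[ReconConfig] = None,
                      support: Optional[np.ndarray] = None):
    """Missing-cone filling by alternating projections (POCS).

    Real space: clamp negative index contrast to zero (the cytoplasm is a
    haemoglobin solution denser than the medium), optionally restricted to
    a support mask.  Fourier space: restore the measured samples (relaxed
    by ``relaxation``).  Returns the regularized volume and the
    data-consistency residual per iteration; the residual sequence is
    non-increasing for relaxation 1 (projections onto convex sets).
    """
    cfg = cfg or ReconConfig()
    dv = fv.voxel_size
    k0 = 2.0 * math.pi / (fv.wavelength_nm * 1e-3)
    meas = fv.averaged
    mask = fv.mask
    meas_norm = np.linalg.norm(meas[mask])
    if meas_norm == 0:
        meas_norm = 1.0

    f = k0 ** 2 * (vol.data ** 2 - vol.n_m ** 2)
    beta = cfg.overrelax
    residuals = []
    prev = None
    for _ in range(cfg.iterations):
        fp = np.where(f < 0.0, 0.0, f)
        if cfg.support_constraint and support is not None:
            fp = np.where(support, fp, 0.0)
        F = ft3c(fp) * dv ** 3
        res = float(np.linalg.norm(F[mask] - meas[mask]) / meas_norm)
        residuals.append(res)
        F[mask] = cfg.relaxation * meas[mask] + \
            (1.0 - cfg.relaxation) * F[mask]
        fp = np.real(ift3c(F)) / dv ** 3
        f = f + beta * (fp - f)
        if prev is not None and abs(prev - res) < cfg.tol:
            break
        prev = res
    f = np.where(f < 0.0, 0.0, f)
    if cfg.support_constraint and support is not None:
        f = np.where(support, f, 0.0)
    out = RIVolume(data=_potential_to_ri(f, fv.n_m, k0), voxel_size=dv,
                   n_m=fv.n_m, wavelength_nm=fv.wavelength_nm)
    return out, residuals


def reconstruct(fields: Sequence[ComplexField2D], optical_cfg,
                recon_cfg: Optional[ReconConfig] = None):
    """map_ewald → invert → regularize_nonneg in one call."""
    recon_cfg = recon_cfg or ReconConfig()
    fv = map_ewald(fields, optical_cfg)
    vol = invert(fv, recon_cfg)
    if recon_cfg.iterations > 0:
        vol, residuals = regularize_nonneg(vol, fv, recon_cfg)
    else:
        residuals = []
    return vol, fv, residuals
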