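"""Ground-truthed red-blood-cell phantoms.

A discocyte is modelled as a solid of revolution whose thickness profile is
an even polynomial under a square-root envelope (the Evans–Fung family):

    T(ρ) = sqrt(1 − (ρ/R)²) · (c0 + c2 (ρ/R)² + c4 (ρ/R)⁴),   0 ≤ ρ ≤ R

with all coefficients in μm.  The choice c2 = c4 = 0, c0 = 2R degenerates to
a sphere of radius R, which anchors the closed-form volume/surface checks.
The cytoplasm is a homogeneous haemoglobin solution: its refractive index is
n_m + α·[Hb] with refraction increment α (mL/g).

Ground-truth volume has the closed form

    V = 2π R² (c0/3 + 2 c2/15 + 8 c4/105)

and the surface area is the surface-of-revolution integral of the upper and
lower faces z = ±T(ρ)/2, evaluated by adaptive quadrature after the
regularising substitution ρ = R sin t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.ndimage import gaussian_filter

from .containers import HeightSeries, RIVolume

__all__ = [
    "DiscocyteSpec",
    "FluctuationSpec",
    "GroundTruth",
    "CohortSpec",
    "CellPhantom",
    "make_discocyte",
    "make_fluctuating_membrane",
    "make_cohort",
    "EVANS_FUNG_COEFFS",
]

# Classic biconcave discocyte coefficients (R, c0, c2, c4 in μm);
# V ≈ 94 fL, rim thickness ≈ 2.6 μm, dimple ≈ 0.8 μm.
EVANS_FUNG_COEFFS = {"R": 3.91, "c0": 0.81, "c2": 7.83, "c4": -4.39}

ALPHA_DEFAULT = 0.18  # refraction increment of haemoglobin, mL/g
N_MEDIUM_DEFAULT = 1.337  # phosphate-buffered saline at 532 nm


class InvalidSpecError(ValueError):
    """Raised for physically impossible phantom specifications."""


class GridOverflowError(ValueError):
    """Raised when a phantom does not fit inside the requested grid."""


@dataclass
class DiscocyteSpec:
    """Shape + composition of a single phantom cell.

    ``hb_true`` is the cytoplasmic haemoglobin concentration in g/dL; the
    cytoplasm index is n_m + alpha * hb_true / 100 (g/dL → g/mL).
    """

    R: float = EVANS_FUNG_COEFFS["R"]
    c0: float = EVANS_FUNG_COEFFS["c0"]
    c2: float = EVANS_FUNG_COEFFS["c2"]
    c4: float = EVANS_FUNG_COEFFS["c4"]
    hb_true: float = 33.4
    center: Optional[Sequence[float]] = None  # (x, y, z) μm; None → grid centre
    tilt: tuple = (0.0, 0.0)  # (about x, about y), rad
    alpha: float = ALPHA_DEFAULT

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise InvalidSpecError("equatorial radius R must be positive")
        if self.hb_true < 0:
            raise InvalidSpecError("hb_true must be non-negative")
        u = np.linspace(0.0, 1.0, 2001)
        if np.any(self._poly(u) < -1e-12):
            raise InvalidSpecError(
                "thickness profile is negative somewhere in [0, R]"
            )

    def _poly(self, u: np.ndarray) -> np.ndarray:
        u2 = np.square(u)
        return self.c0 + self.c2 * u2 + self.c4 * u2 * u2

    def thickness(self, rho) -> np.ndarray:
        """T(ρ) in μm; zero outside the equatorial radius."""
        rho = np.asarray(rho, dtype=float)
        u = np.clip(rho / self.R, 0.0, None)
        inside = u <= 1.0
        env = np.sqrt(np.clip(1.0 - u * u, 0.0, None))
        return np.where(inside, env * self._poly(np.minimum(u, 1.0)), 0.0)

    def scaled_to_volume(self, volume_fl: float) -> "DiscocyteSpec":
        """Isotropically rescaled copy with the requested volume (fL)."""
        if volume_fl <= 0:
            raise InvalidSpecError("target volume must be positive")
        s = (volume_fl / analytic_volume(self)) ** (1.0 / 3.0)
        return DiscocyteSpec(
            R=self.R * s, c0=self.c0 * s, c2=self.c2 * s, c4=self.c4 * s,
            hb_true=self.hb_true, center=self.center, tilt=self.tilt,
            alpha=self.alpha,
        )


@dataclass
class FluctuationSpec:
    """Stochastic membrane-motion parameters.

    sigma_target is the prescribed spatially averaged temporal SD of the
    height maps (nm); frame_rate/duration default to the 125 Hz × 2.4 s
    acquisition used for fluctuation imaging.
    """

    sigma_target: float = 50.0  # nm
    n_modes: int = 24
    corr_time: float = 0.0  # s; 0 → temporally i.i.d. frames
    corr_length: float = 0.7  # μm, spatial smoothness of the modes
    frame_rate: float = 125.0  # Hz
    duration: float = 2.4  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_target < 0:
            raise InvalidSpecError("sigma_target must be non-negative")
        if self.n_frames < 2:
            raise InvalidSpecError("need at least 2 frames")
        if self.n_modes < 1:
            raise InvalidSpecError("need at least one spatial mode")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))


@dataclass
class GroundTruth:
    """True values of the six per-cell parameters for a phantom."""

    volume_fl: float
    surface_um2: float
    sphericity: float
    hb_g_dl: float
    hb_pg: float
    sigma_nm: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.sphericity <= 1.0 + 1e-12):
            raise ValueError("sphericity must lie in (0, 1]")


@dataclass
class CellPhantom:
    """A cohort entry: per-cell spec pair plus its ground truth."""

    cell_id: str
    subject_id: str
    group: str
    shape: DiscocyteSpec
    fluct: FluctuationSpec
    truth: GroundTruth


@dataclass
class CohortSpec:
    """Two-group cohort layout and per-group parameter distributions.

    ``groups`` maps group name → dict with per-parameter ``{"mean": m,
    "sd": s}`` entries for volume_fl, hb_g_dl, sigma_nm, plus a list
    ``hba1c_pct`` of per-subject glycated-haemoglobin levels.  A fraction
    ``between_subject_fraction`` of each group SD is attributed to
    subject-to-subject variation, the rest to cell-to-cell variation.
    """

    n_subjects: int = 6
    n_cells: int = 40
    groups: dict = dc_field(default_factory=dict)
    between_subject_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_cells < 1:
            raise InvalidSpecError("n_subjects and n_cells must be >= 1")
        if not 0.0 <= self.between_subject_fraction < 1.0:
            raise InvalidSpecError("between_subject_fraction must be in [0, 1)")
        for g, params in self.groups.items():
            for key in ("volume_fl", "hb_g_dl", "sigma_nm"):
                if params[key]["sd"] < 0:
                    raise InvalidSpecError(f"{g}/{key}: sd must be >= 0")


# ---------------------------------------------------------------------------
# analytic morphometry of the profile


def analytic_volume(spec: DiscocyteSpec) -> float:
    """Closed-form volume 2π∫ρT(ρ)dρ in fL."""
    return (
        2.0 * math.pi * spec.R ** 2
        * (spec.c0 / 3.0 + 2.0 * spec.c2 / 15.0 + 8.0 * spec.c4 / 105.0)
    )


def analytic_surface(spec: DiscocyteSpec) -> float:
    """Surface area (μm²) of the two faces z = ±T(ρ)/2 by quadrature.

    Substituting ρ = R sin t removes the square-root singularity of T′ at
    the rim, leaving a smooth integrand on [0, π/2].
    """

    R, c0, c2, c4 = spec.R, spec.c0, spec.c2, spec.c4

    def integrand(t: float) -> float:
        s, c = math.sin(t), math.cos(t)
        u2 = s * s
        poly = c0 + c2 * u2 + c4 * u2 * u2
        dpoly = 2.0 * c2 * s + 4.0 * c4 * s * u2
        # T(u)=c·poly(u), u=s;  dT/dρ = (1/R)·dT/du = (−s·poly/c + c·dpoly)/R
        # integrand ρ·sqrt(1+(T′/2)²)·dρ = R s·sqrt(1+(T′/2)²)·R c dt; the
        # factor c regularises the 1/c blow-up of T′ at the rim:
        # c·sqrt(1+(T′/2)²) = sqrt(c² + (c T′/2)²), c·T′ = (−s poly + c² dpoly)/R
        cT = (-s * poly + c * c * dpoly) / R
        return R * R * s * math.sqrt(c * c + 0.25 * cT * cT)

    val, _ = quad(integrand, 0.0, math.pi / 2.0, limit=200)
    return 2.0 * 2.0 * math.pi * val  # 2π azimuth × (top + bottom face)


def sphericity_index(volume_fl: float, surface_um2: float) -> float:
    """Normalised volume-to-surface ratio: 1 for a sphere, → 0 for a disk."""
    if surface_um2 <= 0:
        raise ValueError("surface area must be positive")
    return (6.0 * volume_fl) ** (2.0 / 3.0) * math.pi ** (1.0 / 3.0) / surface_um2


def ground_truth(spec: DiscocyteSpec, sigma_nm: float = 0.0) -> GroundTruth:
    V = analytic_volume(spec)
    S = analytic_surface(spec)
    hb = spec.hb_true
    return GroundTruth(
        volume_fl=V,
        surface_um2=S,
        sphericity=sphericity_index(V, S),
        hb_g_dl=hb,
        hb_pg=hb * V * 0.01,
        sigma_nm=sigma_nm,
    )


# ---------------------------------------------------------------------------
# voxelisation


def make_discocyte(
    spec: DiscocyteSpec,
    voxel_size: float,
    grid_dims: Sequence[int],
    n_m: float = N_MEDIUM_DEFAULT,
    wavelength_nm: float = 532.0,
) -> tuple:
    """Voxelise a discocyte into an RIVolume with its GroundTruth.

    Cytoplasm voxels get n = n_m + α·[Hb]; voxels straddling the upper or
    lower face get a fractional-fill weighted index, which suppresses
    voxelisation bias in downstream volume estimates.  Ground-truth V and S
    come from the analytic integrals, not from voxel counting.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    nz, ny, nx = (int(d) for d in grid_dims)
    if spec.center is None:
        cx, cy, cz = (
            (nx // 2) * voxel_size,
            (ny // 2) * voxel_size,
            (nz // 2) * voxel_size,
        )
    else:
        cx, cy, cz = spec.center

    half_T0 = 0.5 * float(np.max(spec.thickness(np.linspace(0, spec.R, 512))))
    for name, c, half_extent, n in (
        ("x", cx, spec.R, nx),
        ("y", cy, spec.R, ny),
        ("z", cz, half_T0, nz),
    ):
        if c - half_extent < 0 or c + half_extent > (n - 1) * voxel_size:
            raise GridOverflowError(
                f"phantom exceeds the grid along {name} "
                f"(centre {c:.2f} μm, half-extent {half_extent:.2f} μm)"
            )

    x = np.arange(nx) * voxel_size - cx
    y = np.arange(ny) * voxel_size - cy
    z = np.arange(nz) * voxel_size - cz
    rho = np.hypot(y[:, None], x[None, :])
    half_thick = 0.5 * spec.thickness(rho)  # (ny, nx)

    # fractional fill along z: overlap of the voxel slab [z−dv/2, z+dv/2]
    # with the cell interval [−T/2, T/2]
    zc = z[:, None, None]
    H = half_thick[None, :, :]
    lo = np.maximum(zc - 0.5 * voxel_size, -H)
    hi = np.minimum(zc + 0.5 * voxel_size, H)
    fill = np.clip((hi - lo) / voxel_size, 0.0, 1.0)
    dn_cyto = spec.alpha * spec.hb_true / 100.0  # g/dL → g/mL
    data = n_m + dn_cyto * fill
    vol = RIVolume(data=data, voxel_size=voxel_size, n_m=n_m,
                   wavelength_nm=wavelength_nm)
    return vol, ground_truth(spec)


# ---------------------------------------------------------------------------
# dynamic membranes


def make_fluctuating_membrane(
    spec: DiscocyteSpec,
    fspec: FluctuationSpec,
    pixel_size: float = 0.1,
    grid_dims: Sequence[int] = (96, 96),
) -> tuple:
    """Synthesize a stochastic height-map time series for one cell.

    The static profile is the cell thickness T(ρ); the perturbation is a sum
    of ``n_modes`` smooth random spatial modes with independent stationary
    unit-variance temporal amplitudes — an Ornstein–Uhlenbeck process with
    correlation time ``corr_time`` (i.i.d. frames when 0).  Mode amplitudes
    are scaled once so the ensemble per-pixel SD averages to sigma_target
    over the projected support; the realized spatial-mean temporal SD then
    converges to sigma_target as the number of frames grows.
    """
    ny, nx = (int(d) for d in grid_dims)
    cx, cy = (nx // 2) * pixel_size, (ny // 2) * pixel_size
    x = np.arange(nx) * pixel_size - cx
    y = np.arange(ny) * pixel_size - cy
    rho = np.hypot(y[:, None], x[None, :])
    h0_nm = spec.thickness(rho) * 1e3  # μm → nm
    support = h0_nm > 0
    if not support.any():
        raise InvalidSpecError("cell support has zero projected area")

    rng = np.random.default_rng(fspec.seed)
    n_frames = fspec.n_frames

    if fspec.sigma_target == 0:
        h = np.broadcast_to(h0_nm, (n_frames, ny, nx)).copy()
        return (
            HeightSeries(h, pixel_size, fspec.frame_rate, support=support),
            ground_truth(spec, sigma_nm=0.0),
        )

    sigma_px = fspec.corr_length / pixel_size
    modes = np.empty((fspec.n_modes, ny, nx))
    for m in range(fspec.n_modes):
        raw = gaussian_filter(rng.standard_normal((ny, nx)), sigma_px)
        modes[m] = np.where(support, raw, 0.0)

    ens_sd = np.sqrt(np.sum(modes ** 2, axis=0))  # per-pixel ensemble SD
    mean_sd = float(np.mean(ens_sd[support]))
    if mean_sd == 0:
        raise InvalidSpecError("degenerate spatial modes (zero variance)")
    modes *= fspec.sigma_target / mean_sd

    # stationary unit-variance AR(1) amplitudes
    if fspec.corr_time > 0:
        phi = math.exp(-1.0 / (fspec.frame_rate * fspec.corr_time))
    else:
        phi = 0.0
    eps = rng.standard_normal((n_frames, fspec.n_modes))
    amps = np.empty_like(eps)
    amps[0] = eps[0]
    w = math.sqrt(1.0 - phi * phi)
    for t in range(1, n_frames):
        amps[t] = phi * amps[t - 1] + w * eps[t]

    h = h0_nm[None, :, :] + np.tensordot(amps, modes, axes=(1, 0))
    return (
        HeightSeries(h, pixel_size, fspec.frame_rate, support=support),
        ground_truth(spec, sigma_nm=fspec.sigma_target),
    )


# ---------------------------------------------------------------------------
# cohorts


def _truncated_normal(rng, mean, sd, low, size=None):
    """Normal draw re-sampled above ``low`` (guards non-physical values)."""
    out = rng.normal(mean, sd, size=size)
    bad = out <= low
    tries = 0
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=np.shape(out)), out)
        bad = out <= low
        tries += 1
        if tries > 100:
            out = np.where(bad, low + abs(mean - low) * 0.1, out)
            break
    return out


def make_cohort(cohort: CohortSpec) -> list:
    """Draw per-cell phantom specs for a two-group cohort.

    Returns one dict per subject: ``{"subject_id", "group", "hba1c_pct",
    "cells": [CellPhantom, ...]}``.  Each subject receives a subject-level
    offset (fraction ``between_subject_fraction`` of the group SD) and cells
    scatter around it with the complementary SD, so the marginal per-cell
    distribution matches the stated group mean and SD.
    """
    rng = np.random.default_rng(cohort.seed)
    subjects: list = []
    f_b = cohort.between_subject_fraction
    f_w = math.sqrt(max(0.0, 1.0 - f_b * f_b))
    for group, params in cohort.groups.items():
        hba1c = list(params.get("hba1c_pct", []))
        for s_idx in range(cohort.n_subjects):
            sid = f"{group[0]}{s_idx + 1}"
            subj_mean = {}
            for key in ("volume_fl", "hb_g_dl", "sigma_nm"):
                m, sd = params[key]["mean"], params[key]["sd"]
                subj_mean[key] = float(rng.normal(m, f_b * sd))
            cells = []
            for c_idx in range(cohort.n_cells):
                V = float(_truncated_normal(
                    rng, subj_mean["volume_fl"],
                    f_w * params["volume_fl"]["sd"], 30.0))
                hb = float(_truncated_normal(
                    rng, subj_mean["hb_g_dl"],
                    f_w * params["hb_g_dl"]["sd"], 10.0))
                sig = float(_truncated_normal(
                    rng, subj_mean["sigma_nm"],
                    f_w * params["sigma_nm"]["sd"], 5.0))
                shape = DiscocyteSpec(hb_true=hb).scaled_to_volume(V)
                fluct = FluctuationSpec(
                    sigma_target=sig,
                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                )
                cells.append(
                    CellPhantom(
                        cell_id=f"{sid}_c{c_idx + 1:03d}",
                        subject_id=sid,
                        group=group,
                        shape=shape,
                        fluct=fluct,
                        truth=ground_truth(shape, sigma_nm=sig),
                    )
                )
            subjects.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "hba1c_pct": float(hba1c[s_idx]) if s_idx < len(hba1c)
                    else float("nan"),
                    "cells": cells,
                }
            )
    return subjects
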