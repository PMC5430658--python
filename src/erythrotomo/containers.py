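"""Shared in-memory containers for the tomography pipeline.

Conventions used throughout the package:

* lengths in micrometres (μm) unless a field name says otherwise
  (wavelengths in nm at the user surface, heights/fluctuations in nm),
* volumes in femtolitres (1 fL = 1 μm³), areas in μm²,
* haemoglobin concentration in g/dL, haemoglobin content in pg,
* wavevectors in rad/μm, spatial frequencies in cycles/μm,
* 3-D arrays are indexed ``[z, y, x]``, 2-D arrays ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RIVolume",
    "ComplexField2D",
    "Interferogram",
    "HeightSeries",
    "CellRecord",
    "SubjectRecord",
]


@dataclass
class RIVolume:
    """A 3-D refractive-index map n(x, y, z).

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        Refractive index per voxel.
    voxel_size : float
        Isotropic voxel pitch in μm.
    n_m : float
        Refractive index of the immersion medium (the buffer the cell
        sits in); contrast is measured as ``data - n_m``.
    wavelength_nm : float, optional
        Vacuum wavelength the indices refer to.
    """

    data: np.ndarray
    voxel_size: float
    n_m: float
    wavelength_nm: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("RIVolume.data must be 3-D (z, y, x)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def delta_n(self) -> np.ndarray:
        """Index contrast relative to the medium."""
        return self.data - self.n_m

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class ComplexField2D:
    """A retrieved (or synthesized) complex optical field at the sample plane.

    The field is stored relative to the incident plane wave, i.e. a blank
    field of view is identically 1.  ``k_in`` is the full 3-D illumination
    wavevector in the medium, |k_in| = 2π n_m / λ.
    """

    field: np.ndarray
    pixel_size: float
    k_in: np.ndarray
    wavelength_nm: float
    n_m: float

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=complex)
        if self.field.ndim != 2:
            raise ValueError("field must be 2-D (y, x)")
        self.k_in = np.asarray(self.k_in, dtype=float)
        if self.k_in.shape != (3,):
            raise ValueError("k_in must be a 3-vector (kx, ky, kz)")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.field)

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase in (−π, π]."""
        return np.angle(self.field)


@dataclass
class Interferogram:
    """An off-axis fringe-modulated intensity image.

    ``carrier`` is the spatial frequency (cycles/μm, (fx, fy)) of the
    reference-beam tilt; the +1 diffraction order in the spectrum sits at
    +carrier and holds the sample field.
    """

    intensity: np.ndarray
    pixel_size: float
    carrier: np.ndarray
    k_in: np.ndarray
    wavelength_nm: float
    n_m: float
    source_shape: Optional[tuple] = None
    band_limit: Optional[float] = None  # cycles/μm, detection cut-off

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2-D")
        if np.min(self.intensity) < 0:
            raise ValueError("interferogram intensity must be non-negative")
        self.carrier = np.asarray(self.carrier, dtype=float)
        self.k_in = np.asarray(self.k_in, dtype=float)


@dataclass
class HeightSeries:
    """Membrane height maps h(x, y, t) in nm at a fixed frame rate."""

    heights_nm: np.ndarray  # (t, y, x)
    pixel_size: float  # μm
    frame_rate: float  # Hz
    support: Optional[np.ndarray] = None  # projected cell footprint

    def __post_init__(self) -> None:
        self.heights_nm = np.asarray(self.heights_nm, dtype=float)
        if self.heights_nm.ndim != 3:
            raise ValueError("heights must be 3-D (t, y, x)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.heights_nm.shape[0]


@dataclass
class CellRecord:
    """The six single-cell parameters plus the mean index contrast.

    volume_fl, surface_um2 and sphericity are morphological; hb_g_dl and
    hb_pg biochemical; sigma_nm is the mean membrane fluctuation.  By
    construction ``hb_pg == hb_g_dl * volume_fl * 0.01``.
    """

    cell_id: str
    volume_fl: float
    surface_um2: float
    sphericity: float
    hb_g_dl: float
    hb_pg: float
    sigma_nm: float
    mean_dn: float
    volume_voxel_fl: Optional[float] = None  # voxel-count volume, QC only
    subject_id: Optional[str] = None
    group: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "subject_id": self.subject_id,
            "group": self.group,
            "volume_fl": self.volume_fl,
            "surface_um2": self.surface_um2,
            "sphericity": self.sphericity,
            "hb_g_dl": self.hb_g_dl,
            "hb_pg": self.hb_pg,
            "sigma_nm": self.sigma_nm,
            "mean_dn": self.mean_dn,
            "volume_voxel_fl": self.volume_voxel_fl,
        }


@dataclass
class SubjectRecord:
    """One blood donor: their cells and the per-subject parameter means.

    Group tests treat the mean over a subject's cells as a single data
    point, so each subject contributes one value per parameter.
    """

    subject_id: str
    group: str
    hba1c_pct: float
    cells: list = field(default_factory=list)

    _PARAMS = ("volume_fl", "surface_um2", "sphericity", "hb_g_dl", "hb_pg", "sigma_nm")

    def __post_init__(self) -> None:
        if self.group not in ("healthy", "diabetic"):
            raise ValueError("group must be 'healthy' or 'diabetic'")

    @property
    def means(self) -> dict:
        if not self.cells:
            raise ValueError("subject has no cells")
        return {
            p: float(np.mean([getattr(c, p) for c in self.cells]))
            for p in self._PARAMS
        }
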