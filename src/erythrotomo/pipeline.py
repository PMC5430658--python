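"""End-to-end orchestration: simulate → retrieve → reconstruct → measure →
fluctuate → cohort statistics, with per-stage artifacts and a manifest.

The per-cell acquisition mirrors the instrument's two passes: a multi-angle
scan for the 3-D tomogram, then a normal-incidence time series for membrane
fluctuations.  Each simulated frame is carried through the full off-axis
interferogram → field-retrieval loop so retrieval imperfections propagate
into the measured parameters exactly as they would on hardware.
"""

from __future__ import annotations

import hashlib
import json
import math
import platform
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .containers import CellRecord, SubjectRecord
from .cell_params import (
    ALPHA_DEFAULT, DEFAULT_THRESHOLD, fluctuation, hb_content, height_series,
    measure_cell, projection_mask,
)
from .cohort_stats import (
    ancova_slopes, correlations, linear_fit_ci, pooled_t_test,
    summarize_cohort, wilcoxon_rank_sum, load_fluctuation_table,
)
from .holography import RetrievalConfig, retrieve_field
from .io import (
    dump_yaml, load_cohort_defaults, write_fields_h5, write_heights_h5,
    write_records_csv, write_volume_tiff,
)
from .optics_forward import (
    OpticalConfig, illumination_wavevectors, make_field, make_interferogram,
)
from .synthetic_cell import (
    CellPhantom, CohortSpec, DiscocyteSpec, FluctuationSpec, make_cohort,
    make_discocyte, make_fluctuating_membrane,
)
from .tomography import ReconConfig, reconstruct

__all__ = ["PipelineConfig", "demo_config", "acquire_cell", "run_pipeline",
           "generate_fixtures"]


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible cohort run."""

    optical: OpticalConfig = dc_field(default_factory=OpticalConfig)
    # production profile: over-relaxed projections, longer schedule (the
    # plain-POCS ReconConfig defaults underconverge on whole cells)
    recon: ReconConfig = dc_field(
        default_factory=lambda: ReconConfig(iterations=300, overrelax=1.85,
                                            tol=0.0))
    retrieval: RetrievalConfig = dc_field(default_factory=RetrievalConfig)
    cohort: Optional[CohortSpec] = None
    threshold: float = DEFAULT_THRESHOLD
    alpha: float = ALPHA_DEFAULT
    forward_model: str = "rytov"
    demodulate: bool = True  # carry frames through the interferogram loop
    fluct_frames: Optional[int] = None  # None → FluctuationSpec default
    seed: int = 0
    outdir: Optional[str] = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def demo_config(seed: int = 0, outdir: Optional[str] = None,
                n_subjects: int = 2, n_cells: int = 3,
                grid: int = 64, n_angles: int = 60) -> PipelineConfig:
    """Desk-scale configuration: small cohort, 64³ grid, 60 angles.

    150 nm voxels give a 9.6 μm field of view so a full-size (~8 μm)
    discocyte fits in 64³; the fluctuation series is shortened to 120
    frames.
    """
    cohort = load_cohort_defaults(n_subjects=n_subjects, n_cells=n_cells,
                                  seed=seed)
    optical = OpticalConfig(detector_dims=(grid, grid), n_angles=n_angles,
                            pixel_size_sample=9.6 / grid)
    return PipelineConfig(optical=optical, cohort=cohort, seed=seed,
                          outdir=outdir, fluct_frames=120)


def _forward_retrieve(vol, k_in, cfg: PipelineConfig):
    fld = make_field(vol, k_in, cfg.optical, model=cfg.forward_model)
    if not cfg.demodulate:
        return fld
    ig = make_interferogram(fld, cfg.optical)
    return retrieve_field(ig, cfg.retrieval)


def acquire_cell(phantom: CellPhantom, cfg: PipelineConfig) -> CellRecord:
    """Simulate and measure one cell end to end."""
    n = cfg.optical.detector_dims[0]
    dv = cfg.optical.pixel_size_sample
    vol_true, truth = make_discocyte(
        phantom.shape, voxel_size=dv, grid_dims=(n, n, n),
        n_m=cfg.optical.n_m, wavelength_nm=cfg.optical.wavelength_nm)

    ks = illumination_wavevectors(cfg.optical)
    fields = [_forward_retrieve(vol_true, k, cfg) for k in ks]
    vol_rec, _, _ = reconstruct(fields, cfg.optical, cfg.recon)
    rec = measure_cell(vol_rec, threshold=cfg.threshold, alpha=cfg.alpha,
                       cell_id=phantom.cell_id)

    # normal-incidence time series
    fspec = phantom.fluct
    if cfg.fluct_frames is not None:
        fspec = FluctuationSpec(
            sigma_target=fspec.sigma_target, n_modes=fspec.n_modes,
            corr_time=fspec.corr_time, corr_length=fspec.corr_length,
            frame_rate=fspec.frame_rate,
            duration=cfg.fluct_frames / fspec.frame_rate, seed=fspec.seed)
    hs_true, _ = make_fluctuating_membrane(
        phantom.shape, fspec, pixel_size=dv, grid_dims=(n, n))
    k0 = 2.0 * math.pi / (cfg.optical.wavelength_nm * 1e-3)
    dn_true = phantom.shape.alpha * phantom.shape.hb_true / 100.0
    phases_true = k0 * dn_true * hs_true.heights_nm * 1e-3  # nm → μm

    if cfg.demodulate:
        from .containers import ComplexField2D
        from .holography import _border_mask, unwrap_phase

        k_norm = np.array([0.0, 0.0, cfg.optical.k_medium])
        bg = _border_mask(phases_true.shape[1:])
        phases = np.empty_like(phases_true)
        for t in range(phases_true.shape[0]):
            fld = ComplexField2D(
                field=np.exp(1j * phases_true[t]), pixel_size=dv,
                k_in=k_norm, wavelength_nm=cfg.optical.wavelength_nm,
                n_m=cfg.optical.n_m)
            ig = make_interferogram(fld, cfg.optical)
            ret = retrieve_field(ig, cfg.retrieval)
            ph = unwrap_phase(np.angle(ret.field))
            phases[t] = ph - ph[bg].mean()  # per-frame piston removal
    else:
        phases = phases_true

    pmask = projection_mask(phases.mean(axis=0))
    hs_meas = height_series(phases, rec.mean_dn, cfg.optical.wavelength_nm,
                            fspec.frame_rate, dv)
    _, sigma = fluctuation(hs_meas, mask=pmask)

    rec.sigma_nm = sigma
    rec.subject_id = phantom.subject_id
    rec.group = phantom.group
    return rec


def _cohort_stats(subjects: list) -> dict:
    """The statistical layer over a measured cohort."""
    out: dict = {}
    groups = sorted({s.group for s in subjects})
    summary = summarize_cohort(subjects)
    out["summary"] = summary.to_dict(orient="records")

    params = ("volume_fl", "surface_um2", "sphericity", "hb_g_dl", "hb_pg",
              "sigma_nm")
    if len(groups) == 2:
        g1, g2 = groups
        s1 = [s for s in subjects if s.group == g1]
        s2 = [s for s in subjects if s.group == g2]
        out["wilcoxon_subject_means"] = {
            p: wilcoxon_rank_sum([s.means[p] for s in s1],
                                 [s.means[p] for s in s2]).as_dict()
            for p in params}
        cells1 = {p: [getattr(c, p) for s in s1 for c in s.cells]
                  for p in params}
        cells2 = {p: [getattr(c, p) for s in s2 for c in s.cells]
                  for p in params}
        if min(len(cells1["sigma_nm"]), len(cells2["sigma_nm"])) >= 2:
            out["pooled_t_cells"] = {
                p: pooled_t_test(cells1[p], cells2[p]).as_dict()
                for p in params}
        # volume vs Hb content: the slope estimates [Hb] in g/dL
        fits = {}
        for g, cells in ((g1, cells1), (g2, cells2)):
            if len(set(cells["volume_fl"])) >= 3:
                fits[g] = linear_fit_ci(cells["volume_fl"],
                                        [v * 100 for v in cells["hb_pg"]]
                                        ).as_dict()
        out["volume_vs_hb_content_fit"] = fits
        if all(len(set(c["volume_fl"])) >= 3 for c in (cells1, cells2)):
            out["volume_vs_hb_content_ancova"] = ancova_slopes(
                cells1["volume_fl"], [v * 100 for v in cells1["hb_pg"]],
                cells2["volume_fl"], [v * 100 for v in cells2["hb_pg"]],
            ).as_dict()
    # σ_h vs HbA1c per group (subject level)
    corr = {}
    for g in groups:
        grp = [s for s in subjects if s.group == g]
        x = [s.hba1c_pct for s in grp]
        y = [s.means["sigma_nm"] for s in grp]
        if len(grp) >= 3 and np.all(np.isfinite(x)) and len(set(x)) > 1:
            corr[g] = correlations(x, y)
    out["sigma_vs_hba1c"] = corr
    return out


def run_pipeline(cfg: PipelineConfig):
    """Run a full cohort and return (records DataFrame, stats dict).

    With ``cfg.outdir`` set, writes cohort.csv, subjects.csv, stats.json
    and manifest.json (plus one example tomogram per group).
    """
    t0 = time.time()
    cohort = cfg.cohort or load_cohort_defaults(seed=cfg.seed)
    subjects_spec = make_cohort(cohort)
    subjects: list = []
    records: list = []
    examples = {}
    for subj in subjects_spec:
        sr = SubjectRecord(subject_id=subj["subject_id"], group=subj["group"],
                           hba1c_pct=subj["hba1c_pct"])
        for phantom in subj["cells"]:
            try:
                rec = acquire_cell(phantom, cfg)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(
                    f"pipeline failed at cell {phantom.cell_id} "
                    f"(subject {subj['subject_id']}): {exc}") from exc
            sr.cells.append(rec)
            records.append(rec)
        subjects.append(sr)

    stats = _cohort_stats(subjects)
    df = pd.DataFrame([r.as_dict() for r in records])
    subj_df = pd.DataFrame([
        {"subject_id": s.subject_id, "group": s.group,
         "hba1c_pct": s.hba1c_pct, **{f"mean_{k}": v
                                      for k, v in s.means.items()}}
        for s in subjects])

    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "cohort.csv", index=False)
        subj_df.to_csv(out / "subjects.csv", index=False)
        with open(out / "stats.json", "w") as f:
            json.dump(stats, f, indent=2, default=float)
        manifest = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_cells": len(records),
            "elapsed_s": round(time.time() - t0, 2),
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        }
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2)
    return df, stats


def generate_fixtures(outdir, seed: int = 0) -> list:
    """Write small reference fixtures; returns the paths written.

    Contents: the published per-subject fluctuation table, one discocyte
    phantom tomogram (TIFF), a 5-angle retrieved-field stack (HDF5) and a
    short height series (HDF5).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    table = load_fluctuation_table()
    p = out / "fluctuation_subject_means.csv"
    table.to_csv(p, index=False)
    paths.append(p)

    optical = OpticalConfig(detector_dims=(64, 64), n_angles=5,
                            pixel_size_sample=0.15)
    spec = DiscocyteSpec(hb_true=33.4).scaled_to_volume(90.0)
    vol, _ = make_discocyte(spec, voxel_size=optical.pixel_size_sample,
                            grid_dims=(64, 64, 64), n_m=optical.n_m)
    p = out / "phantom_ri.tiff"
    write_volume_tiff(p, vol)
    paths.append(p)

    fields = [make_field(vol, k, optical, model="rytov")
              for k in illumination_wavevectors(optical)]
    p = out / "fields.h5"
    write_fields_h5(p, fields)
    paths.append(p)

    hs, _ = make_fluctuating_membrane(
        spec, FluctuationSpec(sigma_target=50.0, duration=32 / 125.0,
                              seed=seed),
        pixel_size=optical.pixel_size_sample, grid_dims=(64, 64))
    p = out / "heights.h5"
    write_heights_h5(p, hs)
    paths.append(p)
    return paths
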