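"""File I/O: HDF5/TIFF volumes and field stacks, YAML configs, CSV tables.

Every file carries enough attributes (voxel size, medium index, wavelength,
frame rate, illumination wavevectors) to re-run the stage that produced it.
"""

from __future__ import annotations

import importlib.resources
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import CellRecord, ComplexField2D, HeightSeries, RIVolume
from .synthetic_cell import CohortSpec

__all__ = [
    "write_volume_h5", "read_volume_h5",
    "write_volume_tiff", "read_volume_tiff",
    "write_fields_h5", "read_fields_h5",
    "write_heights_h5", "read_heights_h5",
    "records_to_frame", "write_records_csv",
    "load_cohort_defaults", "load_yaml", "dump_yaml",
]


def write_volume_h5(path, vol: RIVolume) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("ri", data=vol.data, compression="gzip", track_times=False)
        d.attrs["voxel_size_um"] = vol.voxel_size
        d.attrs["n_m"] = vol.n_m
        if vol.wavelength_nm is not None:
            d.attrs["wavelength_nm"] = vol.wavelength_nm


def read_volume_h5(path) -> RIVolume:
    with h5py.File(path, "r") as f:
        d = f["ri"]
        return RIVolume(
            data=d[...],
            voxel_size=float(d.attrs["voxel_size_um"]),
            n_m=float(d.attrs["n_m"]),
            wavelength_nm=float(d.attrs.get("wavelength_nm", np.nan)),
        )


def write_volume_tiff(path, vol: RIVolume) -> None:
    tifffile.imwrite(
        path, vol.data.astype(np.float32),
        metadata={"voxel_size_um": vol.voxel_size, "n_m": vol.n_m,
                  "wavelength_nm": vol.wavelength_nm})


def read_volume_tiff(path) -> RIVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return RIVolume(data=data, voxel_size=float(meta["voxel_size_um"]),
                    n_m=float(meta["n_m"]),
                    wavelength_nm=meta.get("wavelength_nm"))


def write_fields_h5(path, fields: Sequence[ComplexField2D]) -> None:
    with h5py.File(path, "w") as f:
        stack = np.stack([fl.field for fl in fields])
        d = f.create_dataset("fields", data=stack, compression="gzip", track_times=False)
        d.attrs["pixel_size_um"] = fields[0].pixel_size
        d.attrs["wavelength_nm"] = fields[0].wavelength_nm
        d.attrs["n_m"] = fields[0].n_m
        f.create_dataset("k_in", data=np.stack([fl.k_in for fl in fields]),
                         track_times=False)


def read_fields_h5(path) -> list:
    with h5py.File(path, "r") as f:
        stack = f["fields"][...]
        k_in = f["k_in"][...]
        px = float(f["fields"].attrs["pixel_size_um"])
        wl = float(f["fields"].attrs["wavelength_nm"])
        n_m = float(f["fields"].attrs["n_m"])
    return [ComplexField2D(field=s, pixel_size=px, k_in=k,
                           wavelength_nm=wl, n_m=n_m)
            for s, k in zip(stack, k_in)]


def write_heights_h5(path, hs: HeightSeries) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("heights_nm", data=hs.heights_nm,
                             compression="gzip", track_times=False)
        d.attrs["pixel_size_um"] = hs.pixel_size
        d.attrs["frame_rate_hz"] = hs.frame_rate
        if hs.support is not None:
            f.create_dataset("support", data=hs.support.astype(np.uint8),
                             track_times=False)


def read_heights_h5(path) -> HeightSeries:
    with h5py.File(path, "r") as f:
        d = f["heights_nm"]
        support = f["support"][...].astype(bool) if "support" in f else None
        return HeightSeries(
            heights_nm=d[...], pixel_size=float(d.attrs["pixel_size_um"]),
            frame_rate=float(d.attrs["frame_rate_hz"]), support=support)


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def write_records_csv(path, records: Sequence[CellRecord]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def load_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def dump_yaml(path, obj: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def load_cohort_defaults(n_subjects: Optional[int] = None,
                         n_cells: Optional[int] = None,
                         seed: int = 0) -> CohortSpec:
    """The packaged two-group cohort preset as a CohortSpec."""
    ref = importlib.resources.files("erythrotomo").joinpath(
        "data/cohort_defaults.yaml")
    with importlib.resources.as_file(ref) as path:
        cfg = load_yaml(path)
    return CohortSpec(
        n_subjects=n_subjects or cfg["n_subjects"],
        n_cells=n_cells or cfg["n_cells"],
        groups=cfg["groups"],
        between_subject_fraction=cfg["between_subject_fraction"],
        seed=seed,
    )
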