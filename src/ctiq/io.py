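"""Reading and writing images, curves and cohort tables.

Images travel either as NPY stacks with a JSON sidecar carrying the grid
geometry (``<name>.npy`` + ``<name>.json``), or as DICOM secondary-capture
series (one file per slice, signed 16-bit HU).  Cohort tables use the tidy
CSV schema defined in :mod:`ctiq.cohort`.
"""

from __future__ import annotations

import json
import os
from glob import glob

import numpy as np
import pandas as pd

from .cohort import PatientRecord, cohort_to_frames
from .grid import ImageGrid

__all__ = [
    "save_image_npy",
    "load_image",
    "save_dicom_series",
    "load_dicom_series",
    "save_cohort_csv",
    "load_cohort_frames",
]


def save_image_npy(grid: ImageGrid, path: str) -> str:
    """Write pixels as ``.npy`` plus a ``.json`` sidecar with the geometry."""
    base, ext = os.path.splitext(path)
    if ext != ".npy":
        base = path
        path = path + ".npy"
    np.save(path, grid.pixels)
    meta = {
        "pixel_spacing_mm": grid.pixel_spacing,
        "slice_thickness_mm": grid.slice_thickness,
        "origin_mm": list(grid.origin),
        "meta": {k: v for k, v in grid.meta.items() if _jsonable(v)},
    }
    with open(base + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None)))


def load_image(path: str, pixel_spacing: float | None = None) -> ImageGrid:
    """Load an image from ``.npy`` (+sidecar) or a DICOM series directory."""
    if os.path.isdir(path):
        return load_dicom_series(path)
    if path.endswith(".npy"):
        pixels = np.load(path)
        sidecar = os.path.splitext(path)[0] + ".json"
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                meta = json.load(fh)
            return ImageGrid(
                pixels,
                pixel_spacing=meta["pixel_spacing_mm"],
                slice_thickness=meta.get("slice_thickness_mm", 0.5),
                origin=tuple(meta.get("origin_mm", (0.0, 0.0))),
                meta=meta.get("meta", {}),
            )
        if pixel_spacing is None:
            raise ValueError(f"no sidecar for {path}; pass pixel_spacing explicitly")
        return ImageGrid(pixels, pixel_spacing=pixel_spacing)
    raise ValueError(f"cannot load image from {path!r}")


def save_dicom_series(grid: ImageGrid, out_dir: str, description: str = "ctiq") -> list[str]:
    """Write the grid as a DICOM secondary-capture series (signed 16-bit HU)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    os.makedirs(out_dir, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for k in range(grid.n_slices):
        sl = np.clip(np.round(grid.slice2d(k)), -32768, 32767).astype(np.int16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.SeriesDescription = description
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = sl.shape
        ds.PixelSpacing = [str(grid.pixel_spacing), str(grid.pixel_spacing)]
        ds.SliceThickness = str(grid.slice_thickness)
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed: HU go below zero
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = "0"
        ds.RescaleSlope = "1"
        ds.PixelData = sl.tobytes()
        path = os.path.join(out_dir, f"slice_{k + 1:04d}.dcm")
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def load_dicom_series(directory: str) -> ImageGrid:
    """Read a directory of single-frame DICOM files into an :class:`ImageGrid`."""
    import pydicom

    files = sorted(glob(os.path.join(directory, "*.dcm")))
    if not files:
        raise ValueError(f"no DICOM files in {directory!r}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    pixels = slices[0] if len(slices) == 1 else np.stack(slices)
    ds0 = datasets[0]
    spacing = float(ds0.PixelSpacing[0]) if hasattr(ds0, "PixelSpacing") else 1.0
    thickness = float(getattr(ds0, "SliceThickness", 0.5))
    return ImageGrid(pixels, pixel_spacing=spacing, slice_thickness=thickness)


def save_cohort_csv(records: list[PatientRecord], out_dir: str) -> dict[str, str]:
    """Write measurements/ratings/doses CSVs; returns the file paths."""
    os.makedirs(out_dir, exist_ok=True)
    m, r, d = cohort_to_frames(records)
    paths = {
        "measurements": os.path.join(out_dir, "measurements.csv"),
        "ratings": os.path.join(out_dir, "ratings.csv"),
        "doses": os.path.join(out_dir, "doses.csv"),
    }
    m.to_csv(paths["measurements"], index=False, float_format="%.10g")
    r.to_csv(paths["ratings"], index=False)
    d.to_csv(paths["doses"], index=False, float_format="%.10g")
    return paths


def load_cohort_frames(
    measurements_csv: str,
    ratings_csv: str | None = None,
    doses_csv: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame | None]:
    m = pd.read_csv(measurements_csv)
    r = pd.read_csv(ratings_csv) if ratings_csv else None
    d = pd.read_csv(doses_csv) if doses_csv else None
    return m, r, d
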