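"""Readers and writers for volumes, masks and the pipeline's tables.

NIfTI (via nibabel) is the canonical interchange format; DICOM series
are supported read-only (via pydicom, with rescale slope/intercept
applied to obtain HU). Axis order of all in-memory arrays is (z, y, x),
0-based; masks and volumes must share shape exactly — no resampling is
ever performed.

Tables (feature table, manifest, stability report, yield summary) are
versioned CSV files; reads validate the schema: unknown columns warn,
missing columns raise.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .phantom import ImageVolume, ROISet

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_table",
    "read_table",
    "TABLE_SCHEMAS",
]

CSV_SCHEMA_VERSION = "1"

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "features": ("feature", "roi_id", "tissue_class", "value",
                 "dose_mGy", "recon_mode", "repeat"),
    "manifest": ("dose_mGy", "repeat", "recon_mode"),
    "report": ("feature", "dose_mGy", "recon_mode", "median_icc",
               "kw_significant_fraction", "mean_occc", "pass_consistency",
               "pass_discrimination", "pass_repeatability",
               "undefined_icc", "undefined_occc", "robust"),
    "summary": ("recon_mode", "dose_mGy", "fraction_consistent",
                "fraction_discriminative", "fraction_repeatable",
                "fraction_robust"),
}


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def _nifti_to_array(img) -> tuple[np.ndarray, tuple[float, float, float]]:
    # nibabel stores (x, y, z); transpose to our (z, y, x) convention
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return np.transpose(data, (2, 1, 0)), (float(zooms[2]), float(zooms[1]),
                                           float(zooms[0]))


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, tuple]:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = [pydicom.dcmread(str(p)) for p in files]
    uids = {getattr(ds, "SeriesInstanceUID", "unknown") for ds in datasets}
    if len(uids) > 1:
        raise ValueError(
            f"directory {directory} mixes {len(uids)} DICOM series: "
            f"{sorted(uids)}"
        )
    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))
    datasets.sort(key=z_of)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            warnings.warn(
                f"DICOM file without rescale tags in {directory}; "
                "assuming identity rescale", stacklevel=2,
            )
            slope, intercept = 1.0, 0.0
        slices.append(arr * float(slope) + float(intercept))
    first = datasets[0]
    dy, dx = (float(v) for v in getattr(first, "PixelSpacing", (1.0, 1.0)))
    dz = float(getattr(first, "SliceThickness", 1.0))
    return np.stack(slices), (dz, dy, dx)


def read_volume(path) -> ImageVolume:
    """Read a NIfTI file or DICOM-series directory into HU voxels (z, y, x)."""
    path = Path(path)
    if path.is_dir():
        voxels, spacing = _read_dicom_series(path)
    else:
        voxels, spacing = _nifti_to_array(nib.load(str(path)))
    return ImageVolume(voxels, spacing, {"source": str(path)})


def write_volume(volume: ImageVolume, path) -> Path:
    """Write a volume as NIfTI (.nii or .nii.gz), spacing in the header."""
    path = Path(path)
    data = np.transpose(volume.voxels, (2, 1, 0))
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
    return path


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def read_mask(path, class_table_path=None, expected_n_rois: int | None = None
              ) -> ROISet:
    """Read an integer NIfTI label map plus its (roi_id, class) CSV table."""
    path = Path(path)
    labels, _ = _nifti_to_array(nib.load(str(path)))
    labels = np.rint(labels).astype(np.int16)
    present = sorted(int(v) for v in np.unique(labels) if v != 0)
    if class_table_path is not None:
        table = pd.read_csv(class_table_path)
        class_of = dict(zip(table["roi_id"].astype(int), table["tissue_class"]))
    else:
        class_of = {i: "unknown" for i in present}
    extraneous = [i for i in present if i not in class_of]
    if extraneous:
        raise ValueError(
            f"mask contains {len(present)} labels but the class table lists "
            f"{len(class_of)}; extraneous labels: {extraneous}"
        )
    if expected_n_rois is not None and len(present) != expected_n_rois:
        raise ValueError(
            f"expected {expected_n_rois} ROIs, mask contains {len(present)}"
        )
    return ROISet(labels, {i: class_of[i] for i in present})


def write_mask(roi_set: ROISet, path, class_table_path=None) -> Path:
    path = Path(path)
    data = np.transpose(roi_set.labels, (2, 1, 0))
    nib.save(nib.Nifti1Image(data.astype(np.int16), np.eye(4)), str(path))
    if class_table_path is not None:
        roi_set.to_table().to_csv(class_table_path, index=False)
    return path


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, kind: str) -> Path:
    """Write a pipeline table as CSV with a schema-version comment line."""
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table is missing columns {missing}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# radstab {kind} v{CSV_SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate a pipeline CSV table."""
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path} contains no {kind} rows")
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table {path} is missing columns {missing}")
    unknown = [c for c in df.columns if c not in TABLE_SCHEMAS[kind]]
    if unknown:
        warnings.warn(f"{kind} table {path} has extra columns {unknown}",
                      stacklevel=2)
    return df
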