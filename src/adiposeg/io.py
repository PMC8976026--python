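"""Readers and writers: NIfTI volumes, 8-bit PNG mask slices, cohort
manifests (JSON), and metric tables (CSV).

The mask codec is the bit-exact mapping between internal class indices
``{0, 1, 2}`` (background, SAT, VAT) and the 8-bit file convention
``{0, 255, 127}``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    CLASS_TO_PIXEL,
    PIXEL_TO_CLASS,
    CohortManifest,
    FormatError,
    LabelMap,
    SegMetrics,
    SubjectRecord,
    VolumeImage,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "encode_mask",
    "decode_mask",
    "write_mask_png",
    "read_mask_png",
    "write_manifest",
    "read_manifest",
    "write_metrics_table",
    "read_metrics_table",
]


# ---------------------------------------------------------------- volumes

def _affine(spacing, origin_z: float) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[2, 3] = origin_z
    return aff


def write_volume(v: VolumeImage, path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz); spacing goes into the header."""
    img = nib.Nifti1Image(np.asarray(v.data), _affine(v.spacing, v.origin_z))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_volume(path) -> VolumeImage:
    """Read a NIfTI-1 volume; intensities are returned unchanged."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin_z = float(img.affine[2, 3])
    return VolumeImage(data=data, spacing=zooms, origin_z=origin_z,
                       subject_id=path.name.split(".")[0])


def write_labelmap(m: LabelMap, path) -> None:
    img = nib.Nifti1Image(m.classes.astype(np.uint8), _affine(m.spacing, 0.0))
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))


def read_labelmap(path) -> LabelMap:
    v = read_volume(path)
    return LabelMap(classes=np.asarray(v.data), spacing=v.spacing,
                    subject_id=v.subject_id)


# ------------------------------------------------------------- mask codec

def encode_mask(m: np.ndarray) -> np.ndarray:
    """Encode a 2-D class slice {0,1,2} as an 8-bit image {0,255,127}."""
    m = np.asarray(m)
    bad = np.setdiff1d(np.unique(m), list(CLASS_TO_PIXEL))
    if bad.size:
        raise FormatError(f"cannot encode class value(s) {bad.tolist()}; "
                          "expected {0,1,2}")
    out = np.zeros(m.shape, dtype=np.uint8)
    for cls, pix in CLASS_TO_PIXEL.items():
        out[m == cls] = pix
    return out


def decode_mask(img: np.ndarray) -> np.ndarray:
    """Decode an 8-bit mask image {0,255,127} to class indices {0,1,2}."""
    img = np.asarray(img)
    bad = np.setdiff1d(np.unique(img), list(PIXEL_TO_CLASS))
    if bad.size:
        raise FormatError(f"cannot decode pixel value(s) {bad.tolist()}; "
                          "expected {0, 127, 255}")
    out = np.zeros(img.shape, dtype=np.uint8)
    for pix, cls in PIXEL_TO_CLASS.items():
        out[img == pix] = cls
    return out


def write_mask_png(m: np.ndarray, path) -> None:
    """Write one mask slice as lossless 8-bit grayscale PNG."""
    iio.imwrite(str(path), encode_mask(m), extension=".png")


def read_mask_png(path) -> np.ndarray:
    img = iio.imread(str(path))
    if img.ndim != 2 or img.dtype != np.uint8:
        raise FormatError(f"{path}: expected 2-D 8-bit grayscale image")
    return decode_mask(img)


# --------------------------------------------------------------- manifest

def write_manifest(m: CohortManifest, path) -> None:
    payload = {"subjects": [dataclasses.asdict(s) for s in m.subjects]}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_manifest(path) -> CohortManifest:
    payload = json.loads(Path(path).read_text())
    return CohortManifest(subjects=[SubjectRecord(**s) for s in payload["subjects"]])


# ----------------------------------------------------------- metric table

def metrics_to_frame(rows: list[SegMetrics]) -> pd.DataFrame:
    """Long-format table: one row per (group, compartment, metric)."""
    if not rows:
        raise ValueError("no metric rows to write")
    recs = []
    for r in rows:
        recs.append({"group": r.group, "compartment": r.compartment,
                     "metric": "dice", "mean": r.dice_mean, "sd": r.dice_sd,
                     "n": r.n_slices})
        recs.append({"group": r.group, "compartment": r.compartment,
                     "metric": "pixel_error_pct", "mean": r.pixel_error_mean_pct,
                     "sd": r.pixel_error_sd_pct, "n": r.n_slices})
    return pd.DataFrame.from_records(recs)


def write_metrics_table(rows: list[SegMetrics], path) -> None:
    """Write the per-group × per-compartment mean ± SD summary as CSV."""
    metrics_to_frame(rows).to_csv(path, index=False)


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
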