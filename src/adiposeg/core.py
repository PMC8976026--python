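"""Core data containers for the fat-segmentation pipeline.

Conventions used throughout the package:

* volumes are indexed ``(x, y, z)``, 0-based, with ``z`` increasing from
  inferior to superior;
* label maps use contiguous class indices ``{0: background, 1: SAT, 2: VAT}``
  internally — the on-disk 8-bit convention ``{0, 255, 127}`` exists only at
  the I/O boundary (:mod:`adiposeg.io`);
* voxel spacing is in millimetres, volumes in millilitres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

BACKGROUND, SAT, VAT = 0, 1, 2
CLASS_NAMES = {BACKGROUND: "background", SAT: "SAT", VAT: "VAT"}
#: on-disk 8-bit grayscale encoding of the three classes
CLASS_TO_PIXEL = {BACKGROUND: 0, SAT: 255, VAT: 127}
PIXEL_TO_CLASS = {v: k for k, v in CLASS_TO_PIXEL.items()}


class FormatError(ValueError):
    """Raised when a file or array violates a format contract."""


@dataclass
class VolumeImage:
    """A 3-D scalar intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary units; must be finite.
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm, all positive.
    origin_z : float
        z offset (mm) of the first slice, used to order stations.
    subject_id : str
        Opaque identifier.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.25, 1.25, 6.0)
    origin_z: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3-D, got {self.data.ndim}-D")
        if min(self.data.shape) < 1:
            raise FormatError(f"degenerate volume dims {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "VolumeImage":
        return replace(self, data=self.data.copy())


@dataclass
class LabelMap:
    """A 3-D class grid over {background, SAT, VAT} aligned to a volume."""

    classes: np.ndarray
    spacing: tuple[float, float, float] = (1.25, 1.25, 6.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 3:
            raise FormatError(f"label map must be 3-D, got {self.classes.ndim}-D")
        bad = np.setdiff1d(np.unique(self.classes), [BACKGROUND, SAT, VAT])
        if bad.size:
            raise FormatError(f"label map contains invalid class values {bad.tolist()}")
        self.classes = self.classes.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.classes.shape

    def class_mask(self, cls: int) -> np.ndarray:
        return self.classes == cls

    def copy(self) -> "LabelMap":
        return replace(self, classes=self.classes.copy())


@dataclass
class SubjectRecord:
    """One row of a cohort manifest."""

    subject_id: str
    group: str  # "control" | "patient"
    age: float
    bmi: float
    volume_path: str = ""
    mask_path: str = ""
    split: str | None = None  # "train" | "val" | "test"


@dataclass
class CohortManifest:
    """Subject-level listing of a (synthetic) cohort with optional splits."""

    subjects: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate subject_id in manifest")

    def by_split(self, split: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.split == split]

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    def __len__(self) -> int:
        return len(self.subjects)


@dataclass
class FatVolumes:
    """SAT and VAT volumes of one examination, in millilitres."""

    sat_ml: float
    vat_ml: float
    subject_id: str = ""
    source: str = "ground_truth"  # "reference" | "predicted" | "ground_truth"

    @property
    def ratio(self) -> float:
        """VAT/SAT ratio; raises if SAT volume is zero."""
        if self.sat_ml <= 0:
            raise ValueError(f"VAT/SAT ratio undefined: SAT volume is {self.sat_ml} mL")
        return self.vat_ml / self.sat_ml


@dataclass
class SegMetrics:
    """Per-class Dice / pixel-error summary of one group of examinations."""

    group: str
    compartment: str  # "SAT" | "VAT"
    dice_mean: float
    dice_sd: float
    pixel_error_mean_pct: float
    pixel_error_sd_pct: float
    n_slices: int
    n_examinations: int


def as_float_volume(data: Sequence | np.ndarray) -> np.ndarray:
    """Coerce to a finite float64 3-D array (validation helper)."""
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 3:
        raise FormatError(f"expected 3-D data, got {arr.ndim}-D")
    if not np.all(np.isfinite(arr)):
        raise FormatError("non-finite intensities")
    return arr
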