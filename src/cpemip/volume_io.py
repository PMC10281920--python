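"""NIfTI I/O and the coordinate conventions shared by the whole pipeline.

All volumes are reoriented to RAS+ on ingest (x increases to the patient's
right, y anteriorly, z superiorly) and voxel values are interpreted as
Hounsfield units clipped to the 12-bit CT range [-1024, 3071].  Every other
module assumes these conventions: axis 0 = x (left-right), axis 1 = y
(antero-posterior), axis 2 = z (vertical).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError, ValidationError

HU_MIN = -1024.0
HU_MAX = 3071.0

#: Canonical class labels: chronic PE, acute PE, negative for PE.
LABELS = ("CPE", "APE", "NEG")

#: Lung mask label codes.
BACKGROUND, LEFT_LUNG, RIGHT_LUNG = 0, 1, 2


@dataclasses.dataclass
class CtVolume:
    """A CT volume in Hounsfield units on a RAS+ voxel lattice.

    Parameters
    ----------
    voxels : (nx, ny, nz) float32 array of HU values.
    spacing : per-axis voxel size in mm, strictly positive.
    affine : 4x4 voxel-index -> world-mm map (RAS+).
    study_id : opaque study identifier.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    study_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def world_coords(self, index: Iterable[float]) -> np.ndarray:
        """World (mm) coordinates of a voxel index."""
        hom = np.append(np.asarray(index, dtype=float), 1.0)
        return (self.affine @ hom)[:3]


@dataclasses.dataclass
class LungMask:
    """Voxel labels {0 background, 1 left lung, 2 right lung} on a CtVolume lattice."""

    labels: np.ndarray
    affine: np.ndarray
    study_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("lung mask must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise FormatError("lung mask labels must be integers")
            self.labels = rounded
        self.labels = self.labels.astype(np.int16)
        extra = set(np.unique(self.labels)) - {BACKGROUND, LEFT_LUNG, RIGHT_LUNG}
        if extra:
            raise FormatError(f"lung mask contains labels outside {{0,1,2}}: {sorted(extra)}")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def side(self, side: str) -> np.ndarray:
        """Boolean support of one lung ('left' or 'right')."""
        return self.labels == side_code(side)


def side_code(side: str) -> int:
    if side == "left":
        return LEFT_LUNG
    if side == "right":
        return RIGHT_LUNG
    raise ValidationError(f"side must be 'left' or 'right', got {side!r}")


@dataclasses.dataclass(frozen=True)
class StudyRecord:
    """Per-study metadata: diagnosis label and optional RV/LV ratio and split tag."""

    study_id: str
    label: str
    rv_lv_ratio: Optional[float] = None
    split_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.rv_lv_ratio is not None and not self.rv_lv_ratio > 0:
            raise ValidationError(f"rv_lv_ratio must be > 0, got {self.rv_lv_ratio}")

    @property
    def is_cpe(self) -> bool:
        return self.label == "CPE"


def read_volume(path: str | Path, study_id: str | None = None) -> CtVolume:
    """Read a 3D NIfTI volume, reorient to RAS+ and clip HU to [-1024, 3071]."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise FormatError(f"expected a 3D NIfTI, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float32)
    data = np.clip(data, HU_MIN, HU_MAX)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CtVolume(data, spacing, img.affine, study_id or path.name.split(".")[0])


def write_volume(volume: CtVolume, path: str | Path) -> None:
    """Write a CtVolume as float32 NIfTI."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, reference: CtVolume) -> LungMask:
    """Read a left/right lung label mask aligned to ``reference``."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D mask, got shape {data.shape}")
    if data.shape != reference.shape:
        raise GeometryError(
            f"mask shape {data.shape} does not match volume shape {reference.shape}"
        )
    return LungMask(data, reference.affine, reference.study_id)


def write_mask(mask: LungMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), mask.affine)
    nib.save(img, str(path))


def read_manifest(path: str | Path) -> list[StudyRecord]:
    """Read a study manifest CSV with columns ``study_id,label[,rv_lv,split]``."""
    df = pd.read_csv(path, dtype={"study_id": str})
    required = {"study_id", "label"}
    if not required.issubset(df.columns):
        raise ValidationError(f"manifest needs columns {sorted(required)}, got {list(df.columns)}")
    if df["study_id"].duplicated().any():
        dupes = df.loc[df["study_id"].duplicated(), "study_id"].tolist()
        raise ValidationError(f"duplicate study_id values: {dupes}")
    records = []
    for row in df.itertuples(index=False):
        rv = getattr(row, "rv_lv", None)
        rv = None if rv is None or pd.isna(rv) else float(rv)
        split = getattr(row, "split", None)
        split = None if split is None or (isinstance(split, float) and pd.isna(split)) else str(split)
        records.append(StudyRecord(str(row.study_id), str(row.label), rv, split))
    return records


def write_manifest(records: Iterable[StudyRecord], path: str | Path) -> None:
    rows = [
        {
            "study_id": r.study_id,
            "label": r.label,
            "rv_lv": r.rv_lv_ratio,
            "split": r.split_tag,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["study_id", "label", "rv_lv", "split"]).to_csv(path, index=False)
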