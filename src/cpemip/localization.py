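"""Sliding-patch occlusion attribution in scanner space.

An axis-aligned cube (80 mm edge by default) is slid through the volume;
everything outside the patch is set to air, the occluded volume is masked
and rendered exactly like an ordinary study, and the classifier's CPE
probability is written back into the patch's voxels, taking the maximum
wherever patches overlap.  The resulting probability map shares the source
volume's grid and affine, so it overlays the CTPA in any viewer.

Patches that do not intersect the selected lung would render a blank view
set whose prediction says nothing about those voxels; they are skipped and
their voxels stay at 0.

Also houses the parenchyma-removal probe: thresholding all voxels below
-500 HU to air before running the pipeline tests whether low-density
parenchymal changes (hypoperfusion) rather than vessel morphology drive
the classification.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import ConfigError, ValidationError
from .mip_render import MipViewSet, TransferFunction, ViewScheme, render_view_set
from .volume_io import HU_MIN, CtVolume, LungMask

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # (lo, hi) per axis


@dataclasses.dataclass
class PatchGrid:
    """Axis-aligned boxes (voxel index ranges) jointly covering the volume."""

    boxes: list[Box]
    edge_mm: float
    stride_mm: float


@dataclasses.dataclass
class LocalizationMap:
    """Per-voxel CPE probability aligned to the source volume."""

    values: np.ndarray  # [0, 1], same shape as the source volume
    affine: np.ndarray
    display_threshold: float = 0.80

    def binarized(self) -> np.ndarray:
        return (self.values >= self.display_threshold).astype(np.uint8)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), str(path))


def make_patch_grid(
    volume: CtVolume, edge_mm: float = 80.0, stride_mm: float | None = None
) -> PatchGrid:
    """Regular lattice of (possibly boundary-clipped) cubes covering the volume."""
    if edge_mm <= 0:
        raise ConfigError("patch edge must be positive")
    stride_mm = edge_mm / 2 if stride_mm is None else stride_mm
    if stride_mm <= 0 or stride_mm > edge_mm:
        raise ConfigError(f"stride {stride_mm} mm must be in (0, edge={edge_mm}]")
    starts_per_axis = []
    edges_vox = []
    for dim, sp in zip(volume.shape, volume.spacing):
        edge_vox = min(max(int(round(edge_mm / sp)), 1), dim)
        stride_vox = max(int(round(stride_mm / sp)), 1)
        starts = list(range(0, max(dim - edge_vox, 0) + 1, stride_vox))
        if starts[-1] + edge_vox < dim:  # clip a final box at the boundary
            starts.append(dim - edge_vox)
        starts_per_axis.append(starts)
        edges_vox.append(edge_vox)
    boxes: list[Box] = []
    for sx in starts_per_axis[0]:
        for sy in starts_per_axis[1]:
            for sz in starts_per_axis[2]:
                boxes.append(
                    (
                        (sx, sx + edges_vox[0]),
                        (sy, sy + edges_vox[1]),
                        (sz, sz + edges_vox[2]),
                    )
                )
    return PatchGrid(boxes, edge_mm, stride_mm)


def _box_slices(box: Box) -> tuple[slice, slice, slice]:
    return tuple(slice(lo, hi) for lo, hi in box)  # type: ignore[return-value]


def occlude_outside(volume: CtVolume, box: Box) -> CtVolume:
    """Keep the patch, set every voxel outside it to -1024 HU."""
    for (lo, hi), dim in zip(box, volume.shape):
        if not 0 <= lo < hi <= dim:
            raise ValidationError(f"box {box} empty or out of bounds for shape {volume.shape}")
    out = np.full(volume.shape, HU_MIN, dtype=np.float32)
    sl = _box_slices(box)
    out[sl] = volume.voxels[sl]
    return CtVolume(out, volume.spacing, volume.affine, volume.study_id)


def localization_map(
    volume: CtVolume,
    mask: LungMask,
    side: str,
    predictor,
    grid: PatchGrid | None = None,
    tf: TransferFunction = TransferFunction(),
    scheme: ViewScheme = ViewScheme(),
    out_px: int = 224,
    iso_mm: float = 1.0,
    display_threshold: float = 0.80,
) -> LocalizationMap:
    """Occlusion attribution for one lung.

    ``predictor`` is anything with ``score_lungs((1, v, px, px)) -> (1,)``
    (a fitted ViewAveragingClassifier or EnsembleClassifier).  Each voxel of
    the map holds the maximum predicted CPE probability over all evaluated
    patches containing it.
    """
    grid = grid or make_patch_grid(volume)
    values = np.zeros(volume.shape, dtype=np.float32)
    support = mask.side(side)
    for box in grid.boxes:
        sl = _box_slices(box)
        if not support[sl].any():
            continue  # patch shows none of this lung
        occluded = occlude_outside(volume, box)
        views = render_view_set(
            occluded, mask, side, tf=tf, scheme=scheme, out_px=out_px, iso_mm=iso_mm
        )
        p = float(predictor.score_lungs(views.images[None])[0])
        values[sl] = np.maximum(values[sl], p)
    return LocalizationMap(values, volume.affine, display_threshold)


def threshold_parenchyma(volume: CtVolume, cutoff: float = -500.0) -> CtVolume:
    """Set every voxel below ``cutoff`` HU to air (-1024 HU)."""
    out = volume.voxels.copy()
    out[out < cutoff] = HU_MIN
    return CtVolume(out, volume.spacing, volume.affine, volume.study_id)
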