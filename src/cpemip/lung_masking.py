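"""Left/right lung masking.

The published pipelines delegate lung segmentation to a dedicated U-net
tool; here that tool's output is consumed via ``method="external_file"``,
while ``method="threshold"`` provides a deterministic, dependency-free
fallback adequate for phantoms and well-aerated chests: voxels below an air
threshold are candidate lung, components touching the volume border
(outside air) are discarded, the two largest components are kept, internal
holes (vessels, bronchi walls) are filled so intrapulmonary vessels survive
masking, and left/right labels are assigned from the world-x coordinate of
each component centroid (RAS+: smaller x = patient's left).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage

from . import volume_io
from .errors import SegmentationError, ValidationError
from .volume_io import CtVolume, LungMask, side_code

#: HU below which a voxel is a lung-candidate (air-ish).
LUNG_HU_THRESHOLD = -400.0


def mask_lungs(
    volume: CtVolume,
    method: str = "threshold",
    mask_file: str | Path | None = None,
    close_mm: float = 12.0,
) -> LungMask:
    """Produce a left/right LungMask for ``volume``.

    Parameters
    ----------
    method : "external_file" to read a precomputed mask NIfTI (``mask_file``),
        "threshold" for the built-in HU-threshold fallback.
    """
    if method == "external_file":
        if mask_file is None:
            raise ValidationError("method='external_file' requires mask_file")
        return volume_io.read_mask(mask_file, volume)
    if method != "threshold":
        raise ValidationError(f"unknown masking method {method!r}")

    candidate = volume.voxels < LUNG_HU_THRESHOLD
    labeled, n = ndimage.label(candidate)
    if n < 2:
        raise SegmentationError(f"found {n} lung-like components, need 2")

    # drop components touching the volume border: outside air
    border = np.zeros_like(labeled, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    border_ids = set(np.unique(labeled[border])) - {0}
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    interior = [(sizes[i - 1], i) for i in range(1, n + 1) if i not in border_ids]
    if len(interior) < 2:
        raise SegmentationError(
            f"found {len(interior)} interior lung-like components, need 2"
        )
    interior.sort(reverse=True)
    keep = [interior[0][1], interior[1][1]]

    # world-x of centroids decides left vs right
    centroids = ndimage.center_of_mass(candidate, labeled, keep)
    world_x = [volume.world_coords(c)[0] for c in centroids]
    left_id, right_id = (keep[0], keep[1]) if world_x[0] < world_x[1] else (keep[1], keep[0])

    # vessels enter each lung through the hilum, so the vessel "tunnel" opens
    # onto the lung surface; a closing of ~close_mm seals that opening before
    # hole filling re-includes the intrapulmonary vessels and bronchi
    close_iter = max(int(np.ceil(close_mm / min(volume.spacing))), 1)
    labels = np.zeros(volume.shape, dtype=np.int16)
    for lung_id, code in ((left_id, volume_io.LEFT_LUNG), (right_id, volume_io.RIGHT_LUNG)):
        comp = labeled == lung_id
        closed = ndimage.binary_closing(comp, iterations=close_iter)
        filled = ndimage.binary_fill_holes(closed | comp)
        labels[filled & ~(labels > 0)] = code
    return LungMask(labels, volume.affine, volume.study_id)


def apply_mask(volume: CtVolume, mask: LungMask, side: str) -> CtVolume:
    """Keep one lung, set everything else to air (-1024 HU)."""
    if mask.shape != volume.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    support = mask.labels == side_code(side)
    if not support.any():
        raise SegmentationError(f"selected lung '{side}' is empty")
    out = np.full(volume.shape, volume_io.HU_MIN, dtype=np.float32)
    out[support] = volume.voxels[support]
    return CtVolume(out, volume.spacing, volume.affine, volume.study_id)
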