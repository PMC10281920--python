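"""Rotational maximum intensity projection rendering.

One lung at a time, the masked HU volume is passed through a fixed
piecewise-linear transfer function, resampled to isotropic spacing, and
projected orthographically along the antero-posterior direction after
rotating the volume about the vertical (z) or left-right horizontal (x)
axis.  The default view scheme is two fans sweeping 150 degrees in
30-degree increments about those two axes, sharing the 0-degree
anteroposterior start view: 6 + 6 - 1 = 11 views.

Augmentation jitters each view by a uniform in-plane 2D rotation and a
uniform perturbation of the 3D projection direction, both drawn from a
seeded generator so training batches are reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigError, ValidationError
from .lung_masking import apply_mask
from .volume_io import CtVolume, LungMask

VERTICAL = "vertical"  # rotation about z, in the x-y plane
HORIZONTAL = "horizontal"  # rotation about x, in the y-z plane

# array axes (RAS+): 0=x, 1=y, 2=z; projection ray runs along y
_ROT_PLANES = {VERTICAL: (0, 1), HORIZONTAL: (1, 2)}
_PROJECTION_AXIS = 1


@dataclasses.dataclass(frozen=True)
class TransferFunction:
    """Monotone HU -> [0, 1] intensity ramp.

    HU at or below ``window_low`` map to 0, at or above ``window_high`` to 1,
    linear in between.  The default window [-100, 500] HU saturates
    contrast-enhanced vessels while suppressing lung parenchyma.
    """

    window_low: float = -100.0
    window_high: float = 500.0

    def __post_init__(self) -> None:
        if not self.window_low < self.window_high:
            raise ConfigError(
                f"degenerate transfer window [{self.window_low}, {self.window_high}]"
            )

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        scaled = (np.asarray(hu, dtype=np.float32) - self.window_low) / (
            self.window_high - self.window_low
        )
        return np.clip(scaled, 0.0, 1.0)


@dataclasses.dataclass(frozen=True)
class ViewScheme:
    """Two rotation fans (vertical then left-right horizontal) sharing the AP start."""

    sweep_deg: float = 150.0
    step_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.sweep_deg < 0:
            raise ConfigError("sweep must be non-negative")
        if self.sweep_deg > 0:
            if self.step_deg <= 0:
                raise ConfigError("step must be positive")
            ratio = self.sweep_deg / self.step_deg
            if abs(ratio - round(ratio)) > 1e-9:
                raise ConfigError(
                    f"sweep {self.sweep_deg} not divisible by step {self.step_deg}"
                )


@dataclasses.dataclass(frozen=True)
class AugmentSpec:
    """Random view jitter: in-plane 2D rotation and 3D direction perturbation."""

    rot2d_deg: float = 3.0
    rot3d_deg: float = 10.0


@dataclasses.dataclass
class MipViewSet:
    """The rendered projection images of one lung with their view directions."""

    images: np.ndarray  # (n_views, px, px) float32 in [0, 1]
    directions: list[tuple[str, float]]
    side: str
    study_id: str = ""

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3 or len(self.directions) != self.images.shape[0]:
            raise ValidationError("one image per view direction required")

    def save_png(self, directory) -> list:
        """Dump each view as an 8-bit PNG for visual inspection."""
        import pathlib

        import imageio.v3 as iio

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for image, (axis, angle) in zip(self.images, self.directions):
            name = f"{self.study_id or 'study'}_{self.side}_{axis}{int(round(angle))}.png"
            iio.imwrite(directory / name, (image * 255).astype(np.uint8))
            paths.append(directory / name)
        return paths


def view_angles(scheme: ViewScheme = ViewScheme()) -> list[tuple[str, float]]:
    """Enumerate the projection directions of a view scheme.

    The anteroposterior 0-degree view is shared by both fans and counted
    once; the default 150/30 scheme yields 11 directions.
    """
    if scheme.sweep_deg == 0:
        return [(VERTICAL, 0.0)]
    n = int(round(scheme.sweep_deg / scheme.step_deg))
    vertical = [(VERTICAL, i * scheme.step_deg) for i in range(n + 1)]
    horizontal = [(HORIZONTAL, i * scheme.step_deg) for i in range(1, n + 1)]
    return vertical + horizontal


def apply_transfer(volume: CtVolume, tf: TransferFunction = TransferFunction()) -> np.ndarray:
    """Map a (masked) HU volume into [0, 1] rendering intensities."""
    return tf(volume.voxels)


def _resample_iso(grid: np.ndarray, spacing: Sequence[float], iso_mm: float) -> np.ndarray:
    factors = tuple(s / iso_mm for s in spacing)
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return grid
    return ndimage.zoom(grid, factors, order=1, mode="constant", cval=0.0)


def _pad_to_cube(grid: np.ndarray) -> np.ndarray:
    # pad to a cube large enough that a single-axis rotation keeps content
    edge = int(math.ceil(max(grid.shape) * 1.5))
    pads = []
    for s in grid.shape:
        total = edge - s
        pads.append((total // 2, total - total // 2))
    return np.pad(grid, pads, mode="constant", constant_values=0.0)


def render_mip(
    grid: np.ndarray,
    direction: tuple[str, float],
    out_px: int | None = None,
    extra_tilt: tuple[str, float] | None = None,
) -> np.ndarray:
    """Orthographic maximum intensity projection of a [0,1] scalar grid.

    The grid (assumed isotropic) is rotated by the view direction, then each
    output pixel takes the maximum along its antero-posterior ray.  Rows of
    the returned image run superior-to-inferior, columns left-to-right.
    """
    axis, angle = direction
    if axis not in _ROT_PLANES:
        raise ConfigError(f"unknown rotation axis {axis!r}")
    rotated = np.asarray(grid, dtype=np.float32)
    if angle % 360.0 != 0.0:
        rotated = ndimage.rotate(
            rotated, angle, axes=_ROT_PLANES[axis], reshape=False, order=1,
            mode="constant", cval=0.0,
        )
    if extra_tilt is not None:
        tilt_axis, tilt_angle = extra_tilt
        if tilt_angle != 0.0:
            rotated = ndimage.rotate(
                rotated, tilt_angle, axes=_ROT_PLANES[tilt_axis], reshape=False,
                order=1, mode="constant", cval=0.0,
            )
    proj = rotated.max(axis=_PROJECTION_AXIS)  # (x, z)
    image = proj.T[::-1, :]  # rows: superior -> inferior, cols: left -> right
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    if out_px is not None:
        image = _letterbox(image, out_px)
    return image


def _letterbox(image: np.ndarray, out_px: int) -> np.ndarray:
    """Scale the image to fit an out_px square, preserving aspect, zero-padded."""
    h, w = image.shape
    scale = out_px / max(h, w)
    scaled = ndimage.zoom(image, scale, order=1, mode="constant", cval=0.0)
    scaled = np.clip(scaled, 0.0, 1.0)
    sh, sw = scaled.shape
    out = np.zeros((out_px, out_px), dtype=np.float32)
    top = (out_px - min(sh, out_px)) // 2
    left = (out_px - min(sw, out_px)) // 2
    out[top : top + min(sh, out_px), left : left + min(sw, out_px)] = scaled[
        :out_px, :out_px
    ]
    return out


def render_view_set(
    volume: CtVolume,
    mask: LungMask,
    side: str,
    tf: TransferFunction = TransferFunction(),
    scheme: ViewScheme = ViewScheme(),
    out_px: int = 224,
    iso_mm: float = 1.0,
    augment: Optional[AugmentSpec] = None,
    seed: int | None = None,
    crop_margin: int = 2,
) -> MipViewSet:
    """Mask one lung, apply the transfer function and render all scheme views.

    With ``augment`` given, every view direction is perturbed by uniform
    +-rot3d_deg about both rotation axes and the projected image receives a
    uniform +-rot2d_deg in-plane rotation, all drawn from ``seed``.
    """
    masked = apply_mask(volume, mask, side)
    transferred = tf(masked.voxels)

    # crop to the lung bounding box (plus margin) for speed
    support = mask.side(side)
    idx = np.nonzero(support)
    lo = [max(int(i.min()) - crop_margin, 0) for i in idx]
    hi = [min(int(i.max()) + crop_margin + 1, s) for i, s in zip(idx, transferred.shape)]
    cropped = transferred[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]

    iso = _resample_iso(cropped, volume.spacing, iso_mm)
    cube = _pad_to_cube(iso)

    rng = np.random.default_rng(seed)
    directions = view_angles(scheme)
    images = []
    for axis, angle in directions:
        if augment is None:
            image = render_mip(cube, (axis, angle), out_px=out_px)
        else:
            jitter_main = rng.uniform(-augment.rot3d_deg, augment.rot3d_deg)
            other = HORIZONTAL if axis == VERTICAL else VERTICAL
            jitter_other = rng.uniform(-augment.rot3d_deg, augment.rot3d_deg)
            image = render_mip(
                cube,
                (axis, angle + jitter_main),
                out_px=None,
                extra_tilt=(other, jitter_other),
            )
            rot2d = rng.uniform(-augment.rot2d_deg, augment.rot2d_deg)
            image = ndimage.rotate(
                image, rot2d, reshape=False, order=1, mode="constant", cval=0.0
            )
            image = _letterbox(np.clip(image, 0.0, 1.0).astype(np.float32), out_px)
        images.append(image)
    return MipViewSet(np.stack(images), directions, side, volume.study_id)
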