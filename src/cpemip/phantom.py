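"""Synthetic chest CT phantoms with class-dependent vascular morphology.

Each phantom is a water-density body containing two ellipsoidal lungs at
parenchymal HU, each perfused by a recursive bifurcating contrast-enhanced
vessel tree whose radii taper by Murray's law (child = parent * 2**(-1/3)).
The diagnosis label controls morphology only:

* ``NEG``  - smooth, fully developed tree;
* ``CPE``  - sinusoidal centerline tortuosity, abrupt calibre steps, and
  random pruning of distal branches (the vascular-remodelling signs a
  reader uses to recognise chronic pulmonary embolism);
* ``APE``  - NEG morphology plus short intraluminal low-HU filling defects
  in proximal branches (fresh clot without remodelling).

Geometry is expressed in fractions of the field of view so the same spec
scales from tiny test grids to CT-like resolutions.  Everything is
deterministic given the spec seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import numpy as np

from . import volume_io
from .errors import ConfigError
from .volume_io import CtVolume, LungMask, StudyRecord

_MIN_SHAPE = 16
_MIN_FOV_MM = 64.0


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic study."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    label: str = "NEG"
    depth: int = 6  # bifurcation levels; full tree has 2**depth tips
    tortuosity_mm: float = 6.0  # CPE centerline sine amplitude
    calibre_step_p: float = 0.3  # CPE abrupt-narrowing probability per branch
    pruning_p: float = 0.5  # CPE distal branch removal probability
    vessel_hu: float = 300.0
    parenchyma_hu: float = -850.0
    body_hu: float = 40.0
    noise_sd: float = 20.0
    seed: int = 0
    #: confine the class-effect morphology to one lung ("left"/"right");
    #: the other lung then grows a NEG-style tree
    unilateral_side: str | None = None

    def __post_init__(self) -> None:
        if self.unilateral_side not in (None, "left", "right"):
            raise ConfigError("unilateral_side must be None, 'left' or 'right'")
        if self.label not in volume_io.LABELS:
            raise ConfigError(f"label must be one of {volume_io.LABELS}")
        if not self.vessel_hu > self.parenchyma_hu:
            raise ConfigError("vessel HU must exceed parenchyma HU")
        for p in (self.calibre_step_p, self.pruning_p):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.tortuosity_mm < 0:
            raise ConfigError("tortuosity amplitude must be >= 0")
        fov = [n * s for n, s in zip(self.shape, self.spacing)]
        if min(self.shape) < _MIN_SHAPE or min(fov) < _MIN_FOV_MM:
            raise ConfigError(
                f"grid {self.shape} @ {self.spacing} mm too small to contain lungs"
            )


@dataclasses.dataclass
class Branch:
    """One vessel segment: centerline points (mm), per-point radii (mm), depth."""

    points: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    depth: int
    is_terminal: bool = False


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    probe = rng.normal(size=3)
    perp = probe - probe.dot(direction) * direction
    while np.linalg.norm(perp) < 1e-6:
        probe = rng.normal(size=3)
        perp = probe - probe.dot(direction) * direction
    return _unit(perp)


def _rotate_toward(direction: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    return _unit(np.cos(angle_rad) * direction + np.sin(angle_rad) * axis)


def grow_vessel_tree(
    spec: PhantomSpec,
    lung_center: np.ndarray,
    lung_semi: np.ndarray,
    medial_sign: float,
    rng: np.random.Generator,
) -> list[Branch]:
    """Grow one lung's bifurcating tree; class effects applied per the label.

    ``medial_sign`` is +1 for the left lung (hilum on its +x side) and -1
    for the right, in RAS+ world coordinates.
    """
    is_cpe = spec.label == "CPE"
    amp = spec.tortuosity_mm if is_cpe else 0.0
    p_step = spec.calibre_step_p if is_cpe else 0.0
    p_prune = spec.pruning_p if is_cpe else 0.0
    prune_start = spec.depth // 2 + 1  # levels strictly distal to this may vanish

    root_start = lung_center + np.array([medial_sign * lung_semi[0] * 0.85, 0.0, lung_semi[2] * 0.15])
    root_dir = _unit(np.array([-medial_sign, 0.15, -0.35]))
    root_len = lung_semi[0] * 0.9
    root_radius = min(lung_semi) * 0.20

    branches: list[Branch] = []
    step_mm = max(min(spec.spacing) * 0.5, 0.75)

    def grow(start: np.ndarray, direction: np.ndarray, length: float, radius: float, depth: int) -> None:
        n_pts = max(int(round(length / step_mm)) + 1, 3)
        t = np.linspace(0.0, 1.0, n_pts)
        pts = start[None, :] + t[:, None] * length * direction[None, :]
        if amp > 0:
            normal = _perpendicular(direction, rng)
            phase = rng.uniform(0, 2 * np.pi)
            cycles = rng.uniform(1.5, 2.5)
            wave = amp * np.sin(2 * np.pi * cycles * t + phase) * np.sin(np.pi * t)
            pts = pts + wave[:, None] * normal[None, :]
        radii = np.full(n_pts, radius)
        if rng.uniform() < p_step:
            cut = rng.uniform(0.3, 0.7)
            radii[t > cut] *= 0.55  # abrupt narrowing
        # keep the centerline inside the lung ellipsoid
        rel = (pts - lung_center) / lung_semi
        inside = (rel**2).sum(axis=1) <= 0.92**2
        if not inside.all():
            last = int(np.argmax(~inside)) if (~inside).any() else n_pts
            last = max(last, 2)
            pts, radii = pts[:last], radii[:last]
        branch = Branch(pts, radii, depth)
        branches.append(branch)
        if depth >= spec.depth:
            branch.is_terminal = True
            return
        end = pts[-1]
        end_dir = _unit(pts[-1] - pts[-2])
        # steer back toward the lung center when close to the boundary
        rel_end = (end - lung_center) / lung_semi
        if (rel_end**2).sum() > 0.55:
            inward = _unit(lung_center - end)
            end_dir = _unit(end_dir + 0.7 * inward)
        axis = _perpendicular(end_dir, rng)
        spread = np.deg2rad(rng.uniform(25.0, 45.0))
        child_len = length * 0.78
        child_radius = radius * 2.0 ** (-1.0 / 3.0)
        pruned_any = False
        for sign in (+1.0, -1.0):
            prune_roll = rng.uniform()
            if depth + 1 >= prune_start and prune_roll < p_prune:
                pruned_any = True
                continue
            child_dir = _rotate_toward(end_dir, sign * axis, spread)
            grow(end, child_dir, child_len, child_radius, depth + 1)
        if pruned_any and all(
            not (b.depth == depth + 1 and np.allclose(b.points[0], end)) for b in branches
        ):
            branch.is_terminal = True

    grow(root_start, root_dir, root_len, root_radius, 0)
    return branches


def tree_stats(branches: list[Branch]) -> dict[str, float]:
    """Morphometry of a generated tree: terminal tips and centerline curvature."""
    tips = sum(1 for b in branches if b.is_terminal)
    curvatures = []
    for b in branches:
        if len(b.points) < 5:
            continue
        d2 = np.diff(b.points, n=2, axis=0)
        ds = np.linalg.norm(np.diff(b.points, axis=0), axis=1).mean()
        curvatures.append(float(np.linalg.norm(d2, axis=1).mean() / max(ds**2, 1e-9)))
    return {
        "tip_count": float(tips),
        "mean_curvature": float(np.mean(curvatures)) if curvatures else 0.0,
        "n_branches": float(len(branches)),
    }


def _ellipsoid(coords: list[np.ndarray], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    acc = np.zeros(tuple(len(c) for c in coords), dtype=np.float64)
    for i, c in enumerate(coords):
        axis_term = ((c - center[i]) / semi[i]) ** 2
        shape = [1, 1, 1]
        shape[i] = -1
        acc = acc + axis_term.reshape(shape)
    return acc <= 1.0


def _stamp_tree(
    voxels: np.ndarray,
    lung_support: np.ndarray,
    branches: list[Branch],
    origin: np.ndarray,
    spacing: np.ndarray,
    hu: float,
) -> None:
    shape = np.array(voxels.shape)
    min_r = 0.55 * float(spacing.min())
    for branch in branches:
        for point, radius in zip(branch.points, branch.radii):
            r = max(float(radius), min_r)
            idx = (point - origin) / spacing
            lo = np.maximum(np.floor(idx - r / spacing).astype(int), 0)
            hi = np.minimum(np.ceil(idx + r / spacing).astype(int) + 1, shape)
            if (lo >= hi).any():
                continue
            sub = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
            grids = np.meshgrid(
                *[(np.arange(a, b) * s + o - p) for a, b, s, o, p in zip(lo, hi, spacing, origin, point)],
                indexing="ij",
            )
            ball = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2 <= r**2
            region = voxels[sub]
            region[ball & lung_support[sub]] = hu
            voxels[sub] = region


def generate_phantom(spec: PhantomSpec) -> tuple[CtVolume, LungMask, StudyRecord]:
    """Generate one labeled phantom study: volume, ground-truth mask, record."""
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape, dtype=int)
    spacing = np.array(spec.spacing, dtype=float)
    fov = shape * spacing
    origin = -(shape - 1) / 2.0 * spacing  # world center at 0
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = origin
    coords = [np.arange(n) * s + o for n, s, o in zip(shape, spacing, origin)]

    voxels = np.full(tuple(shape), volume_io.HU_MIN, dtype=np.float32)
    body = _ellipsoid(coords, np.array([0.0, 0.0, 0.0]), np.array([0.47, 0.42, 0.49]) * fov)
    voxels[body] = spec.body_hu

    lung_semi = np.array([0.175, 0.27, 0.33]) * fov
    centers = {
        "left": np.array([-0.23 * fov[0], 0.02 * fov[1], 0.0]),
        "right": np.array([+0.23 * fov[0], 0.02 * fov[1], 0.0]),
    }
    labels = np.zeros(tuple(shape), dtype=np.int16)
    supports = {}
    for side, code in (("left", volume_io.LEFT_LUNG), ("right", volume_io.RIGHT_LUNG)):
        support = _ellipsoid(coords, centers[side], lung_semi)
        supports[side] = support
        labels[support] = code
        voxels[support] = spec.parenchyma_hu

    trees = {}
    for side in ("left", "right"):
        medial_sign = +1.0 if side == "left" else -1.0
        side_spec = spec
        if spec.unilateral_side is not None and side != spec.unilateral_side:
            side_spec = dataclasses.replace(spec, label="NEG", unilateral_side=None)
        tree = grow_vessel_tree(side_spec, centers[side], lung_semi, medial_sign, rng)
        trees[side] = tree
        _stamp_tree(voxels, supports[side], tree, origin, spacing, spec.vessel_hu)

    if spec.label == "APE":
        _add_filling_defects(voxels, supports, trees, origin, spacing, rng)

    if spec.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, spec.noise_sd, tuple(shape)).astype(np.float32)
    voxels = np.clip(voxels, volume_io.HU_MIN, volume_io.HU_MAX)

    study_id = f"phantom-{spec.label.lower()}-{spec.seed}"
    rv_lv = {"CPE": 1.25, "APE": 0.95, "NEG": 0.85}[spec.label] + float(rng.normal(0, 0.05))
    record = StudyRecord(study_id, spec.label, rv_lv_ratio=max(rv_lv, 0.1))
    volume = CtVolume(voxels, tuple(spacing), affine, study_id)
    mask = LungMask(labels, affine, study_id)
    return volume, mask, record


def _add_filling_defects(
    voxels: np.ndarray,
    supports: dict[str, np.ndarray],
    trees: dict[str, list[Branch]],
    origin: np.ndarray,
    spacing: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Short soft-tissue-density clots inside proximal branches (APE)."""
    clot_hu = 55.0
    for side, tree in trees.items():
        proximal = [b for b in tree if b.depth <= 2]
        if not proximal:
            continue
        for branch in rng.choice(len(proximal), size=min(2, len(proximal)), replace=False):
            b = proximal[int(branch)]
            mid = len(b.points) // 2
            seg = Branch(b.points[mid : mid + 3], b.radii[mid : mid + 3] * 0.85, b.depth)
            _stamp_tree(voxels, supports[side], [seg], origin, spacing, clot_hu)


def generate_cohort_records(
    n_per_class: int,
    seed: int = 0,
    **spec_overrides,
) -> Iterator[tuple[CtVolume, LungMask, StudyRecord]]:
    """Yield ``3 * n_per_class`` in-memory phantom studies, seeds derived from ``seed``."""
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    idx = 0
    for label in volume_io.LABELS:
        for _ in range(n_per_class):
            child_seed = (seed * 9176 + idx * 7919 + 1) % (2**31)
            spec = PhantomSpec(label=label, seed=child_seed, **spec_overrides)
            volume, mask, record = generate_phantom(spec)
            record = StudyRecord(
                f"{record.study_id}-{idx:03d}", record.label, record.rv_lv_ratio
            )
            volume.study_id = record.study_id
            mask.study_id = record.study_id
            yield volume, mask, record
            idx += 1


def generate_cohort(
    n_per_class: int,
    out_dir: str | Path,
    seed: int = 0,
    **spec_overrides,
) -> list[StudyRecord]:
    """Write a cohort to disk: NIfTI volume + mask per study and a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for volume, mask, record in generate_cohort_records(n_per_class, seed, **spec_overrides):
        volume_io.write_volume(volume, out / f"{record.study_id}.nii.gz")
        volume_io.write_mask(mask, out / f"{record.study_id}_mask.nii.gz")
        records.append(record)
    volume_io.write_manifest(records, out / "manifest.csv")
    return records
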