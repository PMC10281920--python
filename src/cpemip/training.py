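"""Dataset splitting, per-lung training with per-epoch checkpointing, and
retrospective checkpoint selection.

Splits are made at study level so a patient's left and right lungs always
share a subset (no leakage between train and test through the paired
lung).  During training each lung is an independent example carrying the
study label, and the example order is reshuffled every epoch from the
seeded generator.  A checkpoint is written after every epoch together with
its early-stopping-set AUC so the best epoch can be selected
retrospectively - including against a different ("local early stopping")
selection set than the one used during the run.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .errors import ValidationError
from .model import ViewAveragingClassifier
from .volume_io import LABELS, StudyRecord

SUBSETS = ("train", "early_stop", "test")


@dataclasses.dataclass
class LungSample:
    """One training/evaluation example: a rendered lung with its study label."""

    study_id: str
    side: str
    label: str  # study-level diagnosis
    views: np.ndarray  # (n_views, px, px)

    @property
    def y(self) -> int:
        return 1 if self.label == "CPE" else 0


@dataclasses.dataclass
class SplitPlan:
    """study_id -> subset assignment; lungs of a study share the subset by construction."""

    assignment: dict[str, str]
    seed: int

    def subset(self, study_id: str) -> str:
        return self.assignment[study_id]

    def studies(self, subset: str) -> list[str]:
        return sorted(s for s, tag in self.assignment.items() if tag == subset)


def assert_no_leakage(plan: SplitPlan) -> None:
    """Each study appears in exactly one subset (dict keys guarantee it; kept
    as an explicit audit run on every plan)."""
    seen: dict[str, str] = {}
    for study, tag in plan.assignment.items():
        if study in seen and seen[study] != tag:
            raise ValidationError(f"study {study} assigned to {seen[study]} and {tag}")
        seen[study] = tag


def _stratified_groups(records: Sequence[StudyRecord]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = defaultdict(list)
    for r in records:
        groups[r.label].append(r.study_id)
    return groups


def make_splits(
    records: Sequence[StudyRecord],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitPlan:
    """Stratified train / early-stop / test split at study level."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label, ids in sorted(_stratified_groups(records).items()):
        if len(ids) < len(SUBSETS):
            raise ValidationError(
                f"class {label} has {len(ids)} studies, fewer than {len(SUBSETS)} subsets"
            )
        ids = list(ids)
        rng.shuffle(ids)
        n = len(ids)
        counts = [int(np.floor(f * n)) for f in fractions]
        remainders = [f * n - c for f, c in zip(fractions, counts)]
        while sum(counts) < n:
            i = int(np.argmax(remainders))
            counts[i] += 1
            remainders[i] = -1
        # every subset gets at least one study of each class
        for i in range(len(counts)):
            while counts[i] == 0:
                j = int(np.argmax(counts))
                counts[j] -= 1
                counts[i] += 1
        pos = 0
        for subset, count in zip(SUBSETS, counts):
            for sid in ids[pos : pos + count]:
                assignment[sid] = subset
            pos += count
    plan = SplitPlan(assignment, seed)
    assert_no_leakage(plan)
    return plan


def make_cv_folds(
    records: Sequence[StudyRecord], k: int = 5, seed: int = 0
) -> list[SplitPlan]:
    """Stratified k-fold plans: fold i validates its studies, trains the rest."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    for label, ids in sorted(_stratified_groups(records).items()):
        if len(ids) < k:
            raise ValidationError(f"class {label} has {len(ids)} studies, fewer than k={k}")
        ids = list(ids)
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            folds[sid] = i % k
    plans = []
    for i in range(k):
        assignment = {sid: ("val" if f == i else "train") for sid, f in folds.items()}
        plan = SplitPlan(assignment, seed)
        assert_no_leakage(plan)
        plans.append(plan)
    return plans


@dataclasses.dataclass
class TrainConfig:
    """Training schedule and model hyperparameters for one run."""

    epochs: int = 30
    seed: int = 0
    augment: bool = False
    checkpoint_dir: str | Path = "checkpoints"
    run_id: int = 0
    backbone: str = "tiny-cnn-test"
    head_widths: tuple[int, int] = (256, 64)
    dropout: float = 0.1
    learning_rate: float = 1e-4
    batch_size: int = 8
    freeze_backbone: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


@dataclasses.dataclass
class Checkpoint:
    run_id: int
    epoch: int
    path: Path
    early_stop_auc: float


def samples_to_arrays(samples: Sequence[LungSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.views for s in samples])
    y = np.array([s.y for s in samples], dtype=int)
    return X, y


def lung_scores_frame(scores: np.ndarray, samples: Sequence[LungSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "study_id": [s.study_id for s in samples],
            "side": [s.side for s in samples],
            "label": [s.y for s in samples],
            "p_cpe": scores,
        }
    )


def lrmax_auc(classifier, samples: Sequence[LungSample]) -> float:
    """Study-level AUC of the LR_max fused score."""
    X, _ = samples_to_arrays(samples)
    frame = lung_scores_frame(classifier.score_lungs(X), samples)
    fused = frame.groupby("study_id").agg(p=("p_cpe", "max"), y=("label", "max"))
    return evaluation.roc_auc(fused["p"].to_numpy(), fused["y"].to_numpy()).auc


def train_run(
    train_samples: Sequence[LungSample],
    early_stop_samples: Sequence[LungSample],
    config: TrainConfig,
    view_provider: Optional[Callable[[int], np.ndarray]] = None,
) -> tuple[ViewAveragingClassifier, list[Checkpoint]]:
    """Train one model, checkpointing after every epoch.

    Returns the classifier in its final-epoch state plus one Checkpoint per
    epoch (weights on disk and the early-stopping-set LR_max AUC).
    ``view_provider(epoch)`` may supply freshly augmented training views for
    each epoch (online augmentation).
    """
    if len(train_samples) == 0:
        raise ValidationError("empty training set")
    X, y = samples_to_arrays(train_samples)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")

    run_dir = Path(config.checkpoint_dir) / f"run_{config.run_id}"
    run_dir.mkdir(parents=True, exist_ok=True)
    clf = ViewAveragingClassifier(
        backbone=config.backbone,
        head_widths=config.head_widths,
        dropout=config.dropout,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        freeze_backbone=config.freeze_backbone,
        random_state=config.seed,
    )
    checkpoints: list[Checkpoint] = []
    metrics: list[dict] = []

    def on_epoch(epoch: int, model: ViewAveragingClassifier) -> None:
        path = run_dir / f"epoch_{epoch}.npz"
        np.savez(path, **model.get_weights())
        auc = lrmax_auc(model, early_stop_samples)
        checkpoints.append(Checkpoint(config.run_id, epoch, path, auc))
        metrics.append(
            {
                "epoch": epoch,
                "train_loss": model.history_[-1]["train_loss"],
                "early_stop_auc": auc,
            }
        )

    clf.fit(X, y, epoch_callback=on_epoch, X_provider=view_provider)
    pd.DataFrame(metrics).to_csv(run_dir / "metrics.csv", index=False)
    return clf, checkpoints


def select_checkpoint(
    checkpoints: Sequence[Checkpoint],
    classifier: ViewAveragingClassifier,
    selection_samples: Sequence[LungSample] | None = None,
) -> Checkpoint:
    """Pick the checkpoint with maximal selection-set AUC; ties -> earliest epoch.

    Without ``selection_samples`` the AUCs logged against the run's own
    early-stopping set are used; with them (the "local early stopping"
    variant) each checkpoint is re-scored on the supplied set.
    """
    if len(checkpoints) == 0:
        raise ValidationError("no checkpoints to select from")
    if selection_samples is None:
        aucs = [c.early_stop_auc for c in checkpoints]
    else:
        labels = {s.y for s in selection_samples}
        if len(labels) < 2:
            raise ValidationError("selection set must contain both classes")
        aucs = []
        for ckpt in checkpoints:
            load_checkpoint(classifier, ckpt)
            aucs.append(lrmax_auc(classifier, selection_samples))
    ordered = sorted(zip(checkpoints, aucs), key=lambda t: (-t[1], t[0].epoch))
    best = ordered[0][0]
    load_checkpoint(classifier, best)
    return best


def load_checkpoint(classifier: ViewAveragingClassifier, checkpoint: Checkpoint) -> None:
    with np.load(checkpoint.path) as data:
        classifier.set_weights({k: data[k] for k in data.files})
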