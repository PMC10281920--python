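"""End-to-end desk-scale experiments on synthetic cohorts.

These functions reproduce the study design at phantom scale: render both
lungs of every study, train five models with per-epoch checkpointing and
early-stopping-set checkpoint selection, ensemble them by softmax
averaging, and evaluate AUC and balanced accuracy in LR_max and all-lungs
modes, with a label-shuffled control and an occlusion-localization probe
on unilateral-disease phantoms.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np

from . import evaluation, localization, phantom, training
from .mip_render import AugmentSpec, TransferFunction, ViewScheme, render_view_set
from .model import EnsembleClassifier, ViewAveragingClassifier
from .training import LungSample, TrainConfig


def _child_seed(seed: int, k: int) -> int:
    return (seed * 9973 + 7919 * k + 13) % (2**31)


def render_cohort_samples(
    studies,
    out_px: int = 64,
    iso_mm: float = 4.0,
    tf: TransferFunction = TransferFunction(),
    scheme: ViewScheme = ViewScheme(),
    augment: AugmentSpec | None = None,
    seed: int | None = None,
) -> list[LungSample]:
    """Render both lungs of every (volume, mask, record) study into samples."""
    samples = []
    for volume, mask, record in studies:
        for side in ("left", "right"):
            views = render_view_set(
                volume, mask, side, tf=tf, scheme=scheme, out_px=out_px,
                iso_mm=iso_mm, augment=augment, seed=seed,
            )
            samples.append(LungSample(record.study_id, side, record.label, views.images))
    return samples


def _train_ensemble(
    train_samples: Sequence[LungSample],
    early_samples: Sequence[LungSample],
    n_runs: int,
    epochs: int,
    seed: int,
    checkpoint_dir: Path,
    learning_rate: float,
) -> EnsembleClassifier:
    members = []
    for run in range(n_runs):
        config = TrainConfig(
            epochs=epochs,
            seed=_child_seed(seed, 100 + run),
            checkpoint_dir=checkpoint_dir,
            run_id=run,
            learning_rate=learning_rate,
        )
        clf, checkpoints = training.train_run(train_samples, early_samples, config)
        training.select_checkpoint(checkpoints, clf)  # loads the best epoch in place
        members.append(clf)
    return EnsembleClassifier(members)


def _scores_frame(predictor, samples: Sequence[LungSample]):
    X, _ = training.samples_to_arrays(samples)
    return training.lung_scores_frame(predictor.score_lungs(X), samples)


def run_synthetic_experiment(
    seed: int = 0,
    n_train_per_class: int = 20,
    n_early_per_class: int = 5,
    n_test_per_class: int = 10,
    n_runs: int = 5,
    epochs: int = 10,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    out_px: int = 64,
    iso_mm: float = 4.0,
    learning_rate: float = 1e-3,
    shuffled_control: bool = True,
    checkpoint_dir: str | Path | None = None,
    return_artifacts: bool = False,
) -> dict:
    """Train on a separable phantom cohort and evaluate the ensemble.

    Returns AUCs and balanced accuracies (LR_max and all-lungs modes,
    ad hoc and post hoc operating points), single-model spread, and the
    test AUC of a control whose training labels were shuffled at study
    level.
    """
    cohorts = {}
    for k, (name, n) in enumerate(
        [("train", n_train_per_class), ("early_stop", n_early_per_class), ("test", n_test_per_class)]
    ):
        studies = list(
            phantom.generate_cohort_records(n, seed=_child_seed(seed, k), shape=shape, spacing=spacing)
        )
        cohorts[name] = render_cohort_samples(studies, out_px=out_px, iso_mm=iso_mm)

    tmp = None
    if checkpoint_dir is None:
        tmp = tempfile.TemporaryDirectory()
        checkpoint_dir = tmp.name
    checkpoint_dir = Path(checkpoint_dir)

    ensemble = _train_ensemble(
        cohorts["train"], cohorts["early_stop"], n_runs, epochs, seed,
        checkpoint_dir / "main", learning_rate,
    )

    test_frame = _scores_frame(ensemble, cohorts["test"])
    early_frame = _scores_frame(ensemble, cohorts["early_stop"])
    labels = {s.study_id: s.y for s in cohorts["test"]}
    early_labels = {s.study_id: s.y for s in cohorts["early_stop"]}

    results: dict = {}
    for mode in ("lr_max", "all_lungs"):
        post = evaluation.evaluate(test_frame, labels, mode=mode, threshold_source="post_hoc")
        ref = evaluation.cases_from_predictions(early_frame, early_labels, mode)
        adhoc = evaluation.evaluate(
            test_frame, labels, mode=mode, threshold_source="ad_hoc", reference=ref
        )
        results[f"auc_{mode}"] = post.auc
        results[f"bacc_posthoc_{mode}"] = post.bacc
        results[f"bacc_adhoc_{mode}"] = adhoc.bacc
    member_aucs = []
    for member in ensemble.members:
        frame = _scores_frame(member, cohorts["test"])
        scores, y = evaluation.cases_from_predictions(frame, labels, "lr_max")
        member_aucs.append(evaluation.roc_auc(scores, y).auc)
    results["single_model_auc_mean"] = float(np.mean(member_aucs))
    results["single_model_auc_sd"] = float(np.std(member_aucs))

    if shuffled_control:
        rng = np.random.default_rng(_child_seed(seed, 5))
        pool = cohorts["train"] + cohorts["early_stop"]
        study_ids = sorted({s.study_id for s in pool})
        study_labels = {s.study_id: s.label for s in pool}
        permuted = rng.permutation([study_labels[s] for s in study_ids])
        relabel = dict(zip(study_ids, permuted))
        shuffled = {
            name: [
                LungSample(s.study_id, s.side, relabel[s.study_id], s.views)
                for s in cohorts[name]
            ]
            for name in ("train", "early_stop")
        }
        shuffled_ensemble = _train_ensemble(
            shuffled["train"], shuffled["early_stop"], n_runs, epochs,
            _child_seed(seed, 6), checkpoint_dir / "shuffled", learning_rate,
        )
        frame = _scores_frame(shuffled_ensemble, cohorts["test"])
        scores, y = evaluation.cases_from_predictions(frame, labels, "lr_max")
        results["auc_shuffled_lr_max"] = evaluation.roc_auc(scores, y).auc

    if return_artifacts:
        results["_ensemble"] = ensemble
        results["_cohorts"] = cohorts
        results["_labels"] = labels
    if tmp is not None:
        tmp.cleanup()
    return results


def run_localization_experiment(
    predictor,
    seed: int = 0,
    n_studies: int = 10,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    out_px: int = 64,
    iso_mm: float = 4.0,
    edge_mm: float = 80.0,
    stride_mm: float = 40.0,
) -> dict:
    """Occlusion localization on unilateral-CPE phantoms.

    Each study has the CPE-generative tree in one lung only; a hit is
    scored when the highest-probability voxel of the combined (left+right,
    lung-restricted) occlusion map falls in the diseased lung.
    """
    hits = 0
    sides = []
    for i in range(n_studies):
        diseased = "left" if i % 2 == 0 else "right"
        spec = phantom.PhantomSpec(
            shape=shape, spacing=spacing, label="CPE",
            unilateral_side=diseased, seed=_child_seed(seed, 50 + i),
        )
        volume, mask, _ = phantom.generate_phantom(spec)
        grid = localization.make_patch_grid(volume, edge_mm=edge_mm, stride_mm=stride_mm)
        combined = np.zeros(volume.shape, dtype=np.float32)
        for side in ("left", "right"):
            m = localization.localization_map(
                volume, mask, side, predictor, grid=grid, out_px=out_px, iso_mm=iso_mm
            )
            combined = np.maximum(combined, m.values)
        lung_vals = np.where(mask.labels > 0, combined, -1.0)
        argmax = np.unravel_index(int(np.argmax(lung_vals)), lung_vals.shape)
        hit_side = "left" if mask.labels[argmax] == 1 else "right"
        sides.append((diseased, hit_side))
        hits += int(hit_side == diseased)
    return {"hits": hits, "n_studies": n_studies, "hit_rate": hits / n_studies, "detail": sides}
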