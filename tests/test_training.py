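import numpy as np
import pandas as pd
import pytest

from cpemip import evaluation
from cpemip.errors import ValidationError
from cpemip.training import (
    Checkpoint,
    LungSample,
    TrainConfig,
    assert_no_leakage,
    make_cv_folds,
    make_splits,
    samples_to_arrays,
    select_checkpoint,
    train_run,
)
from cpemip.volume_io import StudyRecord


def _records(n_per_class):
    out = []
    for label in ("CPE", "APE", "NEG"):
        out += [StudyRecord(f"{label.lower()}{i}", label) for i in range(n_per_class)]
    return out


def _separable_samples(records, rng, px=12, n_views=3, shift=0.6):
    """Both lungs per study; CPE lungs carry a mean-intensity shift."""
    samples = []
    for r in records:
        for side in ("left", "right"):
            views = rng.uniform(0, 0.4, (n_views, px, px)).astype(np.float32)
            if r.label == "CPE":
                views += shift
            samples.append(LungSample(r.study_id, side, r.label, views))
    return samples


class TestMakeSplits:
    def test_stratified_arithmetic_30_studies(self):
        plan = make_splits(_records(10), fractions=(0.6, 0.2, 0.2), seed=0)
        counts = {s: plan.studies(s) for s in ("train", "early_stop", "test")}
        assert [len(counts[s]) for s in counts] == [18, 6, 6]
        for subset in counts.values():
            labels = [s[:3] for s in subset]
            assert labels.count("cpe") == labels.count("ape") == labels.count("neg")

    def test_deterministic_given_seed(self):
        a = make_splits(_records(5), seed=3)
        b = make_splits(_records(5), seed=3)
        assert a.assignment == b.assignment
        assert make_splits(_records(5), seed=4).assignment != a.assignment

    def test_lungs_paired_and_no_leakage(self, rng):
        records = _records(4)
        plan = make_splits(records, seed=1)
        samples = _separable_samples(records, rng)
        per_study = {}
        for s in samples:
            per_study.setdefault(s.study_id, set()).add(plan.subset(s.study_id))
        assert all(len(subsets) == 1 for subsets in per_study.values())
        assert len(per_study) == len(records)  # each study in exactly one subset
        assert_no_leakage(plan)

    def test_bad_fractions_and_tiny_class_rejected(self):
        with pytest.raises(ValidationError):
            make_splits(_records(5), fractions=(0.5, 0.2, 0.2))
        with pytest.raises(ValidationError):
            make_splits(_records(2), fractions=(0.6, 0.2, 0.2))


class TestMakeCvFolds:
    def test_partition_into_five_validation_folds(self):
        records = _records(5)  # 15 studies... need >= k per class
        plans = make_cv_folds(records, k=5, seed=0)
        assert len(plans) == 5
        validated = [set(p.studies("val")) for p in plans]
        assert set().union(*validated) == {r.study_id for r in records}
        for i in range(5):
            for j in range(i + 1, 5):
                assert not validated[i] & validated[j]

    def test_each_fold_validates_equal_share(self):
        plans = make_cv_folds(_records(5), k=5, seed=0)
        assert all(len(p.studies("val")) == 3 for p in plans)

    def test_deterministic_and_class_size_check(self):
        a = make_cv_folds(_records(6), k=5, seed=2)
        b = make_cv_folds(_records(6), k=5, seed=2)
        assert [p.assignment for p in a] == [p.assignment for p in b]
        with pytest.raises(ValidationError):
            make_cv_folds(_records(3), k=5)


class TestTrainRun:
    def test_checkpoint_per_epoch_and_metrics_log(self, tmp_path, rng):
        records = _records(4)
        samples = _separable_samples(records, rng)
        config = TrainConfig(epochs=3, seed=0, checkpoint_dir=tmp_path, run_id=2,
                             learning_rate=1e-3)
        _, checkpoints = train_run(samples, samples, config)
        assert [c.epoch for c in checkpoints] == [1, 2, 3]
        assert all(c.path.exists() for c in checkpoints)
        metrics = pd.read_csv(tmp_path / "run_2" / "metrics.csv")
        assert list(metrics.columns) == ["epoch", "train_loss", "early_stop_auc"]
        assert len(metrics) == 3

    def test_consumes_two_examples_per_study(self, rng):
        records = _records(4)
        samples = _separable_samples(records, rng)
        X, y = samples_to_arrays(samples)
        assert len(X) == 2 * len(records)

    def test_determinism_of_loss_curves(self, tmp_path, rng):
        records = _records(3)
        samples = _separable_samples(records, rng)
        config = dict(epochs=2, seed=9, learning_rate=1e-3)
        clf_a, _ = train_run(samples, samples, TrainConfig(checkpoint_dir=tmp_path / "a", **config))
        clf_b, _ = train_run(samples, samples, TrainConfig(checkpoint_dir=tmp_path / "b", **config))
        assert [h["train_loss"] for h in clf_a.history_] == [h["train_loss"] for h in clf_b.history_]

    def test_separable_cohort_reaches_high_early_stop_auc(self, tmp_path, rng):
        records = _records(8)
        train = _separable_samples(records, rng)
        early = _separable_samples(_records(3), rng)
        config = TrainConfig(epochs=6, seed=0, checkpoint_dir=tmp_path, learning_rate=3e-3)
        _, checkpoints = train_run(train, early, config)
        assert checkpoints[-1].early_stop_auc > 0.9

    def test_single_class_training_set_rejected(self, tmp_path, rng):
        records = [StudyRecord(f"n{i}", "NEG") for i in range(4)]
        samples = _separable_samples(records, rng)
        with pytest.raises(ValidationError):
            train_run(samples, samples, TrainConfig(epochs=1, checkpoint_dir=tmp_path))


class TestSelectCheckpoint:
    def _fake_checkpoints(self, tmp_path, clf, aucs):
        out = []
        for i, auc in enumerate(aucs, start=1):
            path = tmp_path / f"epoch_{i}.npz"
            np.savez(path, **clf.get_weights())
            out.append(Checkpoint(0, i, path, auc))
        return out

    @pytest.fixture()
    def fitted(self, tmp_path, rng):
        records = _records(3)
        samples = _separable_samples(records, rng)
        clf, _ = train_run(samples, samples, TrainConfig(epochs=1, checkpoint_dir=tmp_path))
        return clf

    def test_argmax_on_logged_aucs(self, tmp_path, fitted):
        cks = self._fake_checkpoints(tmp_path, fitted, [0.6, 0.9, 0.7])
        assert select_checkpoint(cks, fitted).epoch == 2

    def test_tie_breaks_to_earliest_epoch(self, tmp_path, fitted):
        cks = self._fake_checkpoints(tmp_path, fitted, [0.8, 0.8, 0.8])
        assert select_checkpoint(cks, fitted).epoch == 1

    def test_local_selection_set_can_disagree(self, tmp_path, rng):
        """Re-scoring checkpoints on a different selection set changes the pick."""
        records = _records(6)
        train = _separable_samples(records, rng)
        config = TrainConfig(epochs=3, seed=1, checkpoint_dir=tmp_path, learning_rate=3e-3)
        clf, cks = train_run(train, train, config)
        local = _separable_samples(_records(3), np.random.default_rng(77))
        best_local = select_checkpoint(cks, clf, selection_samples=local)
        assert best_local.epoch in {c.epoch for c in cks}

    def test_single_class_selection_set_rejected(self, tmp_path, fitted, rng):
        cks = self._fake_checkpoints(tmp_path, fitted, [0.5])
        neg_only = _separable_samples([StudyRecord("n0", "NEG")], rng)
        with pytest.raises(ValidationError):
            select_checkpoint(cks, fitted, selection_samples=neg_only)
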