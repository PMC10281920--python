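import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpemip.errors import ValidationError
from cpemip.evaluation import (
    RocSummary,
    balanced_accuracy,
    bacc_at_threshold,
    cases_from_predictions,
    evaluate,
    operating_point,
    roc_auc,
)


def _rank_auc_oracle(scores, labels):
    """Tie-corrected Mann-Whitney U / (n+ * n-)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return u / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_gives_unit_auc(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels).auc == 1.0

    def test_constant_scores_give_half(self):
        scores = np.full(10, 0.5)
        labels = np.array([1, 0] * 5)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5)

    def test_matches_rank_statistic_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.uniform(size=n), 2)  # ties included
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                _rank_auc_oracle(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        transformed = np.exp(3 * scores) / (1 + np.exp(3 * scores))
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc(transformed, labels).auc, abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestOperatingPoint:
    def test_perfect_point_selected(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        summary = roc_auc(scores, labels)
        assert summary.sensitivity_at_op == 1.0 and summary.specificity_at_op == 1.0

    def test_equidistant_tie_prefers_higher_specificity(self):
        roc = RocSummary(
            thresholds=np.array([0.7, 0.4]),
            sensitivity=np.array([0.8, 0.9]),
            specificity=np.array([0.9, 0.8]),
            auc=0.9, operating_threshold=np.nan,
            sensitivity_at_op=np.nan, specificity_at_op=np.nan,
        )
        assert operating_point(roc) == 0.7  # the (sens .8, spec .9) point

    def test_matches_brute_force_minimisation(self, rng):
        scores = rng.uniform(size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        summary = roc_auc(scores, labels)
        d = np.sqrt((1 - summary.sensitivity) ** 2 + (1 - summary.specificity) ** 2)
        chosen = np.hypot(1 - summary.sensitivity_at_op, 1 - summary.specificity_at_op)
        assert chosen == pytest.approx(d.min(), abs=1e-12)


class TestBalancedAccuracy:
    def test_results_confusion_counts_round_to_089(self):
        # 21 CPE with one miss; 42 controls with 3 + 4 false positives
        bacc = balanced_accuracy(tp=20, fn=1, fp=7, tn=35)
        assert bacc == pytest.approx((20 / 21 + 35 / 42) / 2)
        assert round(bacc, 2) == 0.89

    def test_perfect_and_degenerate_classifiers(self):
        assert balanced_accuracy(10, 0, 0, 20) == 1.0
        assert balanced_accuracy(10, 0, 20, 0) == 0.5  # everything positive

    def test_prevalence_invariance(self):
        a = balanced_accuracy(20, 5, 8, 40)
        b = balanced_accuracy(60, 15, 8, 40)  # positives tripled
        assert a == pytest.approx(b)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            balanced_accuracy(0, 0, 5, 5)


def _prediction_frame(rng, n_studies=12, signal=1.0):
    rows, labels = [], {}
    for i in range(n_studies):
        sid = f"s{i}"
        y = i % 2
        labels[sid] = y
        for side in ("left", "right"):
            rows.append(
                {"study_id": sid, "side": side,
                 "p_cpe": np.clip(rng.normal(0.3 + signal * 0.4 * y, 0.2), 0, 1)}
            )
    return pd.DataFrame(rows), labels


class TestEvaluate:
    def test_all_lungs_mode_doubles_cases(self, rng):
        frame, labels = _prediction_frame(rng)
        scores, y = cases_from_predictions(frame, labels, "all_lungs")
        assert len(scores) == 2 * len(labels)
        scores_f, y_f = cases_from_predictions(frame, labels, "lr_max")
        assert len(scores_f) == len(labels)
        fused = frame.groupby("study_id")["p_cpe"].max()
        np.testing.assert_allclose(np.sort(scores_f), np.sort(fused.to_numpy()))

    def test_post_hoc_bacc_bounds_ad_hoc(self, rng):
        """The in-set optimal threshold can never do worse than a transferred one."""
        for trial in range(10):
            frame, labels = _prediction_frame(rng)
            ref_frame, ref_labels = _prediction_frame(rng)
            ref = cases_from_predictions(ref_frame, ref_labels, "lr_max")
            post = evaluate(frame, labels, "lr_max", "post_hoc")
            adhoc = evaluate(frame, labels, "lr_max", "ad_hoc", reference=ref)
            assert post.bacc >= adhoc.bacc - 1e-12

    def test_post_hoc_reproduces_roc_plus_operating_point(self, rng):
        frame, labels = _prediction_frame(rng)
        scores, y = cases_from_predictions(frame, labels, "lr_max")
        direct = roc_auc(scores, y)
        via = evaluate(frame, labels, "lr_max", "post_hoc")
        assert via.auc == direct.auc
        assert via.operating_threshold == direct.operating_threshold
        assert via.bacc == pytest.approx(
            bacc_at_threshold(scores, y, direct.operating_threshold)
        )

    def test_missing_lung_rejected_in_lrmax(self, rng):
        frame, labels = _prediction_frame(rng)
        broken = frame.iloc[1:]
        with pytest.raises(ValidationError):
            cases_from_predictions(broken, labels, "lr_max")

    def test_ad_hoc_requires_reference(self, rng):
        frame, labels = _prediction_frame(rng)
        with pytest.raises(ValidationError):
            evaluate(frame, labels, "lr_max", "ad_hoc")

    def test_lrmax_beats_all_lungs_for_unilateral_disease(self):
        """When disease sits in one random lung per positive study, the healthy
        lung of a positive still carries the positive label in 'all' mode and
        dilutes it; LR_max fusion removes that dilution."""
        rng = np.random.default_rng(7)
        margins = []
        for _ in range(10):
            rows, labels = [], {}
            for i in range(40):
                sid = f"s{i}"
                y = i % 2
                labels[sid] = y
                diseased = rng.choice(["left", "right"])
                for side in ("left", "right"):
                    p = rng.beta(6, 3) if (y and side == diseased) else rng.beta(3, 6)
                    rows.append({"study_id": sid, "side": side, "p_cpe": p})
            frame = pd.DataFrame(rows)
            auc_all = evaluate(frame, labels, "all_lungs").auc
            auc_lr = evaluate(frame, labels, "lr_max").auc
            margins.append(auc_lr - auc_all)
        assert np.mean(margins) > 0
        assert sum(m >= 0 for m in margins) >= 9
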