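"""AUC, operating point and confusion battery against closed forms and brute force."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyverify.metrics import (
    ALL_TOPICS,
    confusion_metrics,
    operating_point,
    per_topic_report,
    roc_auc,
)


def brute_force_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.1], [1, 0], 1.0),
            ([0.1, 0.9], [1, 0], 0.0),
            ([0.5, 0.5, 0.2], [1, 0, 0], 0.75),
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(
        st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 1.0]), min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_pair_counting(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if sum(labels) in (0, len(labels)):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(int)
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(3 * scores), labels) == pytest.approx(a, abs=1e-12)
        assert roc_auc(scores**3 + 2, labels) == pytest.approx(a, abs=1e-12)

    def test_di_ndi_string_labels_accepted(self):
        assert roc_auc([0.9, 0.1], ["DI", "NDI"]) == 1.0


class TestOperatingPoint:
    def test_perfect_separation_reaches_tpr_one(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        t = operating_point(scores, labels, 0.05)
        cm = confusion_metrics(scores, labels, t)
        assert cm["FPR"] == 0.0
        assert cm["Recall"] == 1.0

    def test_identical_scores_threshold_above_all(self):
        scores = [0.5] * 6
        labels = [1, 0, 0, 1, 0, 0]
        t = operating_point(scores, labels, 0.05)
        cm = confusion_metrics(scores, labels, t)
        assert cm["FPR"] == 0.0 and cm["Recall"] == 0.0

    def test_chance_scores_give_tpr_near_fpr(self, rng):
        scores = rng.random(1000)
        labels = (rng.random(1000) < 0.5).astype(int)
        t = operating_point(scores, labels, 0.05)
        cm = confusion_metrics(scores, labels, t)
        assert abs(cm["Recall"] - cm["FPR"]) <= 0.03

    def test_realized_fpr_nonincreasing_in_threshold(self, rng):
        scores = rng.random(300)
        labels = (rng.random(300) < 0.3).astype(int)
        fprs = [
            confusion_metrics(scores, labels, t)["FPR"]
            for t in np.linspace(0, 1.01, 40)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(fprs, fprs[1:]))


class TestConfusionMetrics:
    def test_arithmetic_on_known_confusion(self):
        # realizes TP=2, FP=1, FN=2, TN=15 at threshold 0.7
        scores = [0.9, 0.8, 0.3, 0.2] + [0.85] + [0.1] * 15
        labels = [1, 1, 1, 1] + [0] * 16
        out = confusion_metrics(scores, labels, 0.7)
        assert out["Recall"] == pytest.approx(0.5)
        assert out["Precision"] == pytest.approx(2 / 3)
        assert out["F1"] == pytest.approx(4 / 7)
        assert out["Accuracy"] == pytest.approx(0.85)
        assert out["TNR"] == pytest.approx(15 / 16)
        assert out["FPR"] == pytest.approx(1 / 16)
        assert out["TNR"] + out["FPR"] == pytest.approx(1.0, abs=1e-9)

    def test_no_predicted_positives_convention(self):
        out = confusion_metrics([0.1, 0.2, 0.3], [1, 0, 1], threshold=0.9)
        assert out["Precision"] == 0.0 and out["Recall"] == 0.0 and out["F1"] == 0.0

    def test_no_negatives_guard(self, caplog):
        with caplog.at_level("WARNING", logger="polyverify.metrics"):
            out = confusion_metrics([0.9, 0.8], [1, 1], threshold=0.1)
        assert out["Recall"] == 1.0
        assert out["FPR"] == 0.0  # undefined, guarded to 0 with a warning
        assert "undefined" in caplog.text


def _synthetic_oof(rng, n_screen=80, topics=("a", "b"), k=4, signal=2.0):
    rows = []
    for i in range(n_screen):
        for t in topics:
            y = rng.random() < 0.25
            score = 1 / (1 + np.exp(-(signal * (1 if y else -1) + rng.normal())))
            rows.append(
                dict(screening_id=f"S{i}", topic=t, fold=i % k,
                     score=score, label="DI" if y else "NDI")
            )
    return pd.DataFrame(rows)


class TestPerTopicReport:
    def test_di_counts_match_labels(self, rng):
        oof = _synthetic_oof(rng)
        rep = per_topic_report(oof)
        for t in ("a", "b"):
            assert rep.frame.loc[t, "n_DI"] == (
                (oof["topic"] == t) & (oof["label"] == "DI")
            ).sum()
        assert rep.frame.loc[ALL_TOPICS, "n_DI"] == (oof["label"] == "DI").sum()

    def test_per_fold_fpr_respects_budget(self, rng):
        oof = _synthetic_oof(rng)
        rep = per_topic_report(oof, max_fpr=0.05)
        ff = rep.fold_frame.dropna(subset=["FPR"])
        assert len(ff) > 0
        assert (ff["FPR"] <= 0.05 + 1e-12).all()

    def test_shuffled_labels_report_chance_auc(self, rng):
        oof = _synthetic_oof(rng, n_screen=300, signal=0.0)
        rep = per_topic_report(oof)
        pooled = roc_auc(oof["score"], oof["label"])
        assert 0.43 <= pooled <= 0.57
        assert 0.40 <= rep.frame.loc[ALL_TOPICS, "ROC_AUC_mean"] <= 0.60

    def test_single_class_fold_excluded_with_warning(self, rng, caplog):
        oof = _synthetic_oof(rng, n_screen=12, k=3)
        oof.loc[(oof["fold"] == 0) & (oof["topic"] == "a"), "label"] = "NDI"
        with caplog.at_level("WARNING", logger="polyverify.metrics"):
            rep = per_topic_report(oof)
        assert "single class" in caplog.text
        sub = rep.fold_frame
        assert sub.loc[(sub["topic"] == "a") & (sub["fold"] == 0), "ROC_AUC"].isna().all()
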