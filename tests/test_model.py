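"""Stacking models: folds, leakage guards, variants, determinism."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import polyverify.model as model_mod
from polyverify.features import build_feature_table
from polyverify.model import (
    SecondOpinionModel,
    TrainConfig,
    make_group_folds,
    score_universal,
    screening_covariates,
    train_one_topic,
    train_two_level,
)
from polyverify.simulate import simulate_cohort

from conftest import tiny_config


def _rows_frame(n_screen, positives, topics=("a",)):
    recs = []
    for i in range(n_screen):
        for t in topics:
            recs.append(
                dict(screening_id=f"S{i:03d}", test_index=0, topic=t,
                     label="DI" if i < positives else "NDI", f0=float(i))
            )
    return pd.DataFrame(recs)


class TestGroupFolds:
    def test_groups_never_split_and_sizes_balance(self):
        rows = _rows_frame(10, 2, topics=("a", "b"))
        fa = make_group_folds(rows, k=5, seed=0)
        sizes = pd.Series(fa.assignment).value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]
        # every row of a screening shares one fold by construction
        mapped = rows["screening_id"].map(fa.assignment)
        assert mapped.groupby(rows["screening_id"]).nunique().eq(1).all()

    def test_stratification_keeps_di_share_in_band(self):
        rows = _rows_frame(100, 20)
        fa = make_group_folds(rows, k=5, seed=3)
        df = fa.to_frame().merge(rows, on="screening_id")
        for _, grp in df.groupby("fold"):
            share = (grp["label"] == "DI").mean()
            assert 0.10 <= share <= 0.30

    def test_too_many_folds_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_group_folds(_rows_frame(5, 1), k=6, seed=0)

    def test_no_positive_screening_errors(self):
        with pytest.raises(ValueError, match="positive"):
            make_group_folds(_rows_frame(6, 0), k=2, seed=0)

    def test_deterministic_given_seed(self):
        rows = _rows_frame(30, 6)
        assert make_group_folds(rows, 5, 9).assignment == make_group_folds(rows, 5, 9).assignment


class TestScoreUniversal:
    def test_mean_and_idempotence(self):
        assert score_universal(0.9, 0.6, 0.3) == pytest.approx(0.6)
        assert score_universal(0.4, 0.4, 0.4) == pytest.approx(0.4)
        assert score_universal(0.0, 0.0, 1.0) == pytest.approx(1 / 3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            score_universal(1.2, 0.5, 0.5)


class TestTwoLevel:
    def test_refit_with_same_seed_reproduces_oof_scores(self, tiny_rows, tiny_cov, tiny_results):
        again = train_two_level(tiny_rows, tiny_cov, config=TrainConfig(seed=7))
        pd.testing.assert_frame_equal(again.oof_scores, tiny_results.oof_scores)

    def test_every_row_scored_exactly_once_in_unit_interval(self, tiny_rows, tiny_results):
        oof = tiny_results.oof_scores
        keys = oof[["screening_id", "topic"]].drop_duplicates()
        expected = tiny_rows[["screening_id", "topic"]].drop_duplicates()
        assert len(keys) == len(expected)
        assert oof["score"].between(0, 1).all()
        assert not oof["score"].isna().any()

    def test_single_class_training_split_errors_naming_fold(self):
        rows = _rows_frame(6, 1, topics=("a",))
        rows[[f"g{i}" for i in range(5)]] = 0.0
        cfg = TrainConfig(k_folds=2, seed=0, alt_fields=())
        with pytest.raises(ValueError, match="fold"):
            SecondOpinionModel(rows, config=cfg).fit()

    def test_unknown_alt_field_errors(self, tiny_rows, tiny_cov):
        with pytest.raises(ValueError, match="unknown alt-data fields"):
            TrainConfig(alt_fields=("shoe_size",)).validate()

    def test_predict_training_screening_returns_stored_oof(self, tiny_rows, tiny_results):
        sid = tiny_rows["screening_id"].iloc[0]
        sub = tiny_rows[tiny_rows["screening_id"] == sid]
        pred = tiny_results.predict(rows=sub)
        stored = tiny_results.oof_scores.query("screening_id == @sid")
        merged = pred.merge(stored, on=["screening_id", "topic"], suffixes=("", "_oof"))
        assert np.allclose(merged["score"], merged["score_oof"])

    def test_predict_unseen_screening_scores_its_topics(self, tiny_results):
        cfg = tiny_config(n_screenings=2, seed=777)
        screenings, _, alt = simulate_cohort(cfg)
        s = screenings[0]
        cov = screening_covariates(screenings, alt)
        out = tiny_results.predict(screening=s, covariates=cov)
        assert sorted(out["topic"]) == sorted(s.conclusions)
        assert out["score"].between(0, 1).all()

    def test_predict_screening_without_relevant_questions_errors(self, tiny_results, tiny_cohort):
        screenings, _, _ = tiny_cohort
        s = dataclasses.replace(screenings[0], screening_id="SX", events=[])
        with pytest.raises(ValueError):
            tiny_results.predict(screening=s)

    def test_summary_mentions_variant_and_auc(self, tiny_results):
        text = tiny_results.summary()
        assert "basic" in text and "OOF AUC" in text


class TestOneTopic:
    def test_training_tables_are_filtered_to_the_topic(self, tiny_rows, tiny_cov, monkeypatch):
        sizes = []
        orig = model_mod.LGBMClassifier.fit

        def spy(self, X, y, *a, **k):
            sizes.append(len(X))
            return orig(self, X, y, *a, **k)

        monkeypatch.setattr(model_mod.LGBMClassifier, "fit", spy)
        res = train_one_topic(tiny_rows, "drug_abuse", tiny_cov, config=TrainConfig(seed=7))
        n_topic_rows = (tiny_rows["topic"] == "drug_abuse").sum()
        k = res.folds.k
        first_level = sizes[::2] if len(sizes) == 2 * k else sizes[:k]
        assert all(s < n_topic_rows for s in first_level)  # < because one fold is held out
        # scoring still covers every topic
        assert set(res.oof_scores["topic"]) == set(tiny_rows["topic"])

    def test_absent_topic_errors(self, tiny_rows, tiny_cov):
        with pytest.raises(ValueError, match="absent"):
            train_one_topic(tiny_rows, "ird_violation", tiny_cov)


class TestInvariants:
    def test_no_screening_spans_folds_in_oof_tables(self, tiny_results):
        for table in (tiny_results.oof_test_scores, tiny_results.oof_scores):
            assert table.groupby("screening_id")["fold"].nunique().eq(1).all()

    def test_stacking_tracks_first_level_under_test_dilution(self):
        cfg = tiny_config(n_screenings=100, per_test_dropout=0.5,
                          tests_per_screening=3, seed=31)
        screenings, _, alt = simulate_cohort(cfg)
        rows = build_feature_table(screenings)
        cov = screening_covariates(screenings, alt)
        res = train_two_level(rows, cov, config=TrainConfig(seed=5))
        assert res.oof_auc >= res.oof_test_auc - 0.02

    def test_rebalancing_keeps_scores_nondegenerate_at_low_prevalence(self):
        cfg = tiny_config(n_screenings=100, deception_prevalence=0.05, seed=17)
        screenings, _, alt = simulate_cohort(cfg)
        rows = build_feature_table(screenings)
        cov = screening_covariates(screenings, alt)
        res = train_two_level(rows, cov, config=TrainConfig(seed=5))
        scores = res.oof_test_scores["score"]
        assert scores.var() > 0
        assert (scores > 0.5).any()
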