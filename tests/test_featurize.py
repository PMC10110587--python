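"""Feature extraction: windows, base stats, the aggregation tree, meta features."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyverify.features import (
    BASE_STATS,
    Q_AGGS,
    aggregate_repetitions,
    base_stats,
    build_feature_row,
    build_feature_table,
    extract_window,
    meta_features,
)
from polyverify.ncca import QuestionEvent, SignalChannel
from polyverify.simulate import simulate_screening

from conftest import micro_config, tiny_config


def _chan(n=1000, rate=31.0):
    return SignalChannel("EDA", rate, np.arange(n, dtype=float))


def _event(start, end, answer):
    return QuestionEvent("Q1", "relevant", "debt", 0, 0, start, end, answer)


class TestExtractWindow:
    def test_window_length_matches_rate_times_duration(self):
        seg = extract_window(_chan(), _event(10.0, 12.0, 15.0), post_answer_s=5.0)
        assert len(seg) == 310  # 31 Hz x 10 s
        assert seg[0] == int(round(10.0 * 31))

    def test_window_beyond_recording_end_errors(self):
        ch = _chan(n=int(31 * 20))
        with pytest.raises(ValueError, match="exceeds"):
            extract_window(ch, _event(10.0, 12.0, 20.0), post_answer_s=5.0)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="empty"):
            extract_window(_chan(), _event(10.0, 10.0, 10.0), post_answer_s=0.0)


class TestBaseStats:
    @pytest.mark.parametrize(
        "seg, expected",
        [
            ([1, 1, 1], dict(min=1, max=1, mean=1, std=0, amplitude=0)),
            (
                [0, 2, 4],
                dict(min=0, max=4, mean=2, std=math.sqrt(8 / 3), amplitude=4),
            ),
            ([-3], dict(min=-3, max=-3, mean=-3, std=0, amplitude=0)),
        ],
    )
    def test_closed_forms(self, seg, expected):
        out = base_stats(np.asarray(seg, dtype=float))
        for k, v in expected.items():
            assert out[k] == pytest.approx(v, abs=1e-12)

    def test_empty_segment_errors(self):
        with pytest.raises(ValueError):
            base_stats(np.array([]))


class TestAggregateRepetitions:
    @pytest.mark.parametrize(
        "vals, expected",
        [
            ([1, 3, 5], dict(min=1, max=5, mean=3, diff=-3)),
            ([0.7], dict(min=0.7, max=0.7, mean=0.7, diff=0.0)),
            ([2, 2, 2, 2], dict(min=2, max=2, mean=2, diff=0.0)),
        ],
    )
    def test_stated_rules(self, vals, expected):
        assert aggregate_repetitions(vals) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_repetitions([])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_order_statistics_bracket_mean(self, vals):
        out = aggregate_repetitions(vals)
        assert out["min"] <= out["mean"] <= out["max"]


class TestMetaFeatures:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([0.2, 0.6, 0.4], (0.2, 0.6, 0.4, 0.2)),
            ([0.7], (0.7, 0.7, 0.7, 0.0)),
            ([0.0, 1.0], (0.0, 1.0, 0.5, 0.5)),
        ],
    )
    def test_stated_formulas(self, scores, expected):
        out = meta_features(scores)
        assert (
            out["pred_proba_min"],
            out["pred_proba_max"],
            out["pred_proba_mean"],
            out["pred_proba_diff"],
        ) == pytest.approx(expected)

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            meta_features([])
        with pytest.raises(ValueError):
            meta_features([0.5, 1.2])


class TestFeatureRow:
    def test_600_uniquely_named_features(self, tiny_cohort):
        screenings, _, _ = tiny_cohort
        row = build_feature_row(screenings[0], 0, "drug_abuse")
        assert len(row.features) == 600
        assert len(set(row.features)) == 600
        assert all(np.isfinite(v) for v in row.features.values())
        assert "EDA_std_mean_max" in row.features  # grammar spot check

    def test_degenerate_hierarchy_collapses_aggregators(self):
        cfg = micro_config()  # 1 question, 1 repetition
        s, _ = simulate_screening(cfg, np.random.default_rng(8))
        row = build_feature_row(s, 0, "drug_abuse")
        f = row.features
        assert len(f) == 600
        for ch in [c.name for c in s.channels]:
            for stat in BASE_STATS:
                for qa in Q_AGGS:
                    assert f[f"{ch}_{stat}_diff_{qa}"] == 0.0
                vals = {f[f"{ch}_{stat}_{ra}_{qa}"] for ra in ("min", "max", "mean")
                        for qa in Q_AGGS}
                assert len(set(np.round(list(vals), 12))) == 1

    def test_missing_topic_errors(self, tiny_cohort):
        screenings, _, _ = tiny_cohort
        with pytest.raises(ValueError):
            build_feature_row(screenings[0], 0, "ird_violation")

    def test_scale_equivariance_of_channel_features(self, tiny_cohort):
        screenings, _, _ = tiny_cohort
        s = screenings[0]
        c = 2.5
        scaled = dataclasses.replace(s)
        scaled.channels = [
            dataclasses.replace(
                ch, samples=ch.samples * c if ch.name == "EDA" else ch.samples
            )
            for ch in s.channels
        ]
        a = build_feature_row(s, 0, "debt").features
        b = build_feature_row(scaled, 0, "debt").features
        for name in a:
            factor = c if name.startswith("EDA_") else 1.0
            assert b[name] == pytest.approx(a[name] * factor, rel=1e-9, abs=1e-9)


# independent nested-loop recomputation (no shared code with the package)
def brute_force_features(screening, test_index, topic, post_answer_s=5.0):
    import statistics

    feats = {}
    for ch in screening.channels:
        rate = ch.sampling_rate_hz
        per_question = {}
        for ev in screening.events:
            if ev.qtype != "relevant" or ev.topic != topic or ev.test_index != test_index:
                continue
            i0 = int(round(ev.t_question_start * rate))
            i1 = int(round((ev.t_answer + post_answer_s) * rate))
            seg = [float(x) for x in ch.samples[i0:i1]]
            stats = {
                "min": min(seg),
                "max": max(seg),
                "mean": statistics.fmean(seg),
                "std": statistics.pstdev(seg),
                "amplitude": max(seg) - min(seg),
            }
            per_question.setdefault(ev.question_id, []).append(
                (ev.repetition_index, stats)
            )
        for stat in ("min", "max", "mean", "std", "amplitude"):
            per_q_aggs = {"min": [], "max": [], "mean": [], "diff": []}
            for qid in sorted(per_question):
                vals = [s[stat] for _, s in sorted(per_question[qid])]
                per_q_aggs["min"].append(min(vals))
                per_q_aggs["max"].append(max(vals))
                per_q_aggs["mean"].append(statistics.fmean(vals))
                per_q_aggs["diff"].append(
                    vals[0] - statistics.fmean(vals[1:]) if len(vals) > 1 else 0.0
                )
            for ra in ("min", "max", "mean", "diff"):
                vals = per_q_aggs[ra]
                feats[f"{ch.name}_{stat}_{ra}_min"] = min(vals)
                feats[f"{ch.name}_{stat}_{ra}_max"] = max(vals)
                feats[f"{ch.name}_{stat}_{ra}_mean"] = statistics.fmean(vals)
    return feats


def test_features_match_independent_brute_force(tiny_cohort):
    screenings, _, _ = tiny_cohort
    for s in screenings[:3]:
        row = build_feature_row(s, 1, "corruption")
        oracle = brute_force_features(s, 1, "corruption")
        assert set(row.features) == set(oracle)
        for name, v in oracle.items():
            assert row.features[name] == pytest.approx(v, abs=1e-9)


class TestFeatureTable:
    def test_row_count_is_screenings_by_tests_by_topics(self, tiny_cohort, tiny_rows):
        screenings, _, _ = tiny_cohort
        assert len(tiny_rows) == len(screenings) * 2 * 3
        assert list(tiny_rows.columns[:4]) == ["screening_id", "test_index", "topic", "label"]
        assert tiny_rows.shape[1] == 604

    def test_missing_topic_in_one_test_skips_that_row(self, tiny_cohort, caplog):
        screenings, _, _ = tiny_cohort
        s = dataclasses.replace(screenings[0])
        s.events = [
            ev
            for ev in screenings[0].events
            if not (ev.topic == "debt" and ev.test_index == 1)
        ]
        with caplog.at_level("WARNING", logger="polyverify.features"):
            table = build_feature_table([s])
        assert len(table) == 2 * 3 - 1
        assert "skipping row" in caplog.text

    def test_empty_cohort_gives_empty_table(self):
        assert build_feature_table([]).empty

    def test_labels_copied_from_conclusions(self, tiny_cohort, tiny_rows):
        screenings, _, _ = tiny_cohort
        s = screenings[3]
        sub = tiny_rows[tiny_rows["screening_id"] == s.screening_id]
        for topic, concl in s.conclusions.items():
            assert (sub.loc[sub["topic"] == topic, "label"] == concl).all()
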