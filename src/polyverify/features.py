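"""Stimulus-locked feature extraction: 600 features per (test, topic).

Each relevant question repetition defines an analysis window
``[t_question_start, t_answer + post_answer_s)`` on every channel.  Within
a window five base statistics are computed (min, max, mean, std,
amplitude = max - min).  Per question, the repetition-ordered values of
each base statistic are reduced with four aggregators (min, max, mean,
diff = first repetition - mean of the subsequent ones).  Per (test,
topic), the per-question values are reduced again with three aggregators
(min, max, mean).  With 10 channels this yields

    10 channels x 5 base stats x 4 repetition aggregators
       x 3 question aggregators = 600

named features ``CHANNEL_basestat_repagg_qagg`` (e.g.
``ABS_BLOOD_VOLUME_min_min_mean``), regardless of how many questions or
repetitions the topic actually has.  The row label is the examiner's
DI/NDI conclusion for the topic.

Second-level (meta) features summarise the first-level model's per-test
DI probabilities for one (screening, topic): ``pred_proba_min/max/mean``
and ``pred_proba_diff = max - mean``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ncca import QuestionEvent, Screening, SignalChannel

logger = logging.getLogger(__name__)

BASE_STATS = ("min", "max", "mean", "std", "amplitude")
REP_AGGS = ("min", "max", "mean", "diff")
Q_AGGS = ("min", "max", "mean")

META_FEATURES = ("pred_proba_min", "pred_proba_max", "pred_proba_mean", "pred_proba_diff")


@dataclass
class FeaturizeConfig:
    """Window and centering options for feature extraction.

    post_answer_s
        Seconds kept after the answer; physiological responses outlast the
        spoken answer, so the default extends the window by 5 s.
    comparison_centering
        When on, the mean base statistics of the test's comparison-question
        windows are subtracted, per channel and statistic, from every
        relevant-question window statistic before aggregation.  Off by
        default (keeps the canonical 600-feature semantics).
    """

    post_answer_s: float = 5.0
    comparison_centering: bool = False


def feature_names(channels: Sequence[str]) -> list[str]:
    """The 600 feature names, in fixed (channel, stat, repagg, qagg) order."""
    return [
        f"{ch}_{st}_{ra}_{qa}"
        for ch in channels
        for st in BASE_STATS
        for ra in REP_AGGS
        for qa in Q_AGGS
    ]


def extract_window(
    channel: SignalChannel, event: QuestionEvent, post_answer_s: float = 5.0
) -> np.ndarray:
    """Samples in the half-open window [t_question_start, t_answer + post)."""
    rate = channel.sampling_rate_hz
    i0 = int(round(event.t_question_start * rate))
    i1 = int(round((event.t_answer + post_answer_s) * rate))
    if i1 > len(channel.samples):
        raise ValueError(
            f"window end {event.t_answer + post_answer_s:.3f}s exceeds recording "
            f"({len(channel.samples) / rate:.3f}s) on channel {channel.name}"
        )
    if i1 <= i0:
        raise ValueError(
            f"empty window [{event.t_question_start}, {event.t_answer + post_answer_s})"
        )
    return channel.samples[i0:i1]


def base_stats(segment: np.ndarray) -> dict[str, float]:
    """Five base statistics of a window; std is the population SD."""
    seg = np.asarray(segment, dtype=float)
    if seg.size == 0:
        raise ValueError("empty segment")
    mn, mx = float(seg.min()), float(seg.max())
    return {
        "min": mn,
        "max": mx,
        "mean": float(seg.mean()),
        "std": float(seg.std()),
        "amplitude": mx - mn,
    }


def aggregate_repetitions(values: Sequence[float]) -> dict[str, float]:
    """Reduce repetition-ordered statistic values to min/max/mean/diff.

    ``diff`` contrasts the first repetition with the mean of the later
    ones (habituation signature); it is 0 when there is a single
    repetition.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no repetition values")
    diff = float(arr[0] - arr[1:].mean()) if arr.size > 1 else 0.0
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "diff": diff,
    }


def meta_features(test_scores: Sequence[float]) -> dict[str, float]:
    """Second-level score aggregates for one (screening, topic)."""
    arr = np.asarray(test_scores, dtype=float)
    if arr.size == 0:
        raise ValueError("no first-level scores")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("scores must lie in [0, 1]")
    mx, mean = float(arr.max()), float(arr.mean())
    return {
        "pred_proba_min": float(arr.min()),
        "pred_proba_max": mx,
        "pred_proba_mean": mean,
        "pred_proba_diff": mx - mean,
    }


@dataclass
class FeatureRow:
    """One (screening, test, topic) record with exactly 600 named features."""

    screening_id: str
    test_index: int
    topic: str
    features: dict[str, float]
    label: str | None = None


# --- internal vectorized machinery ---------------------------------------


def _signal_matrix(screening: Screening) -> tuple[np.ndarray, list[str], float]:
    n = min(len(ch.samples) for ch in screening.channels)
    sig = np.vstack([ch.samples[:n] for ch in screening.channels])
    names = [ch.name for ch in screening.channels]
    rate = screening.channels[0].sampling_rate_hz
    return sig, names, rate


def _event_stats(
    sig: np.ndarray, rate: float, event: QuestionEvent, post_answer_s: float
) -> np.ndarray:
    """Base statistics of one event window for all channels: (n_ch, 5)."""
    i0 = int(round(event.t_question_start * rate))
    i1 = int(round((event.t_answer + post_answer_s) * rate))
    if i1 > sig.shape[1]:
        raise ValueError(
            f"window for question {event.question_id!r} (test {event.test_index}) "
            f"exceeds the recording"
        )
    if i1 <= i0:
        raise ValueError(f"empty window for question {event.question_id!r}")
    seg = sig[:, i0:i1]
    mn = seg.min(axis=1)
    mx = seg.max(axis=1)
    return np.column_stack([mn, mx, seg.mean(axis=1), seg.std(axis=1), mx - mn])


def _relevant_stats_by_question(
    screening: Screening,
    test_index: int,
    topic: str,
    cfg: FeaturizeConfig,
    sig: np.ndarray,
    rate: float,
) -> list[np.ndarray]:
    """Per question (sorted by id): array (n_rep, n_ch, 5) in repetition order."""
    events = screening.relevant_events(test_index, topic)
    if not events:
        raise ValueError(
            f"no relevant questions for topic {topic!r} in test {test_index} "
            f"of screening {screening.screening_id}"
        )
    center = None
    if cfg.comparison_centering:
        comp = [
            ev
            for ev in screening.events
            if ev.qtype == "comparison" and ev.test_index == test_index
        ]
        if comp:
            center = np.mean(
                [_event_stats(sig, rate, ev, cfg.post_answer_s) for ev in comp], axis=0
            )
    by_question: dict[str, list[tuple[int, np.ndarray]]] = {}
    for ev in events:
        st = _event_stats(sig, rate, ev, cfg.post_answer_s)
        if center is not None:
            st = st - center
        by_question.setdefault(ev.question_id, []).append((ev.repetition_index, st))
    out = []
    for qid in sorted(by_question):
        reps = sorted(by_question[qid], key=lambda p: p[0])
        out.append(np.stack([st for _, st in reps]))
    return out


def _aggregate(question_arrays: list[np.ndarray]) -> np.ndarray:
    """Two-level reduction to the (n_ch, 5, 4, 3) feature tensor."""
    per_question = []
    for arr in question_arrays:  # arr: (n_rep, n_ch, 5)
        diff = arr[0] - arr[1:].mean(axis=0) if arr.shape[0] > 1 else np.zeros_like(arr[0])
        per_question.append(
            np.stack([arr.min(axis=0), arr.max(axis=0), arr.mean(axis=0), diff])
        )
    q = np.stack(per_question)  # (n_q, 4, n_ch, 5)
    qagg = np.stack([q.min(axis=0), q.max(axis=0), q.mean(axis=0)])  # (3, 4, n_ch, 5)
    # reorder to (n_ch, 5, 4, 3) so the flattened order matches feature_names
    return np.transpose(qagg, (2, 3, 1, 0))


def build_feature_row(
    screening: Screening,
    test_index: int,
    topic: str,
    cfg: FeaturizeConfig | None = None,
) -> FeatureRow:
    """Extract the 600-feature row for one (screening, test, topic)."""
    cfg = cfg or FeaturizeConfig()
    sig, ch_names, rate = _signal_matrix(screening)
    arrays = _relevant_stats_by_question(screening, test_index, topic, cfg, sig, rate)
    tensor = _aggregate(arrays)
    values = tensor.ravel()
    if not np.isfinite(values).all():
        raise ValueError(
            f"non-finite feature for screening {screening.screening_id}, "
            f"test {test_index}, topic {topic}"
        )
    names = feature_names(ch_names)
    return FeatureRow(
        screening_id=screening.screening_id,
        test_index=test_index,
        topic=topic,
        features=dict(zip(names, values.tolist())),
        label=screening.conclusions.get(topic),
    )


def build_feature_table(
    screenings: Iterable[Screening], cfg: FeaturizeConfig | None = None
) -> pd.DataFrame:
    """One row per (screening, test, topic) with relevant questions.

    Rows failing preconditions (e.g. a topic absent from one test) are
    skipped with a logged warning.  Row order is deterministic:
    (screening_id, test_index, topic).
    """
    cfg = cfg or FeaturizeConfig()
    records: list[dict[str, object]] = []
    names: list[str] | None = None
    for s in sorted(screenings, key=lambda s: s.screening_id):
        sig, ch_names, rate = _signal_matrix(s)
        if names is None:
            names = feature_names(ch_names)
        tests = sorted({ev.test_index for ev in s.events})
        topics = sorted({ev.topic for ev in s.events if ev.qtype == "relevant" and ev.topic})
        for test in tests:
            for topic in topics:
                try:
                    arrays = _relevant_stats_by_question(s, test, topic, cfg, sig, rate)
                except ValueError as exc:
                    logger.warning("skipping row: %s", exc)
                    continue
                values = _aggregate(arrays).ravel()
                if not np.isfinite(values).all():
                    logger.warning(
                        "skipping row with non-finite features: %s test %d topic %s",
                        s.screening_id,
                        test,
                        topic,
                    )
                    continue
                rec: dict[str, object] = {
                    "screening_id": s.screening_id,
                    "test_index": test,
                    "topic": topic,
                    "label": s.conclusions.get(topic),
                }
                rec.update(zip(names, values.tolist()))
                records.append(rec)
    cols = ["screening_id", "test_index", "topic", "label"] + (names or [])
    df = pd.DataFrame.from_records(records, columns=cols)
    return df.sort_values(["screening_id", "test_index", "topic"], kind="mergesort").reset_index(
        drop=True
    )


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The 600 feature columns of a table built by :func:`build_feature_table`."""
    meta = {"screening_id", "test_index", "topic", "label"}
    return [c for c in table.columns if c not in meta]
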