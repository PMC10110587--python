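"""Evaluation battery: ROC AUC and confusion metrics at a fixed-FPR point.

The screening context dictates the operating point: flagged conclusions
cost expensive examiner hours, so the threshold is chosen as the smallest
score cutoff whose realized false-positive rate stays at or below a
budget (5 % by default), and sensitivity (TPR) is read off there.  Per
topic and per fold the battery reports ROC AUC, Recall, Precision, F1,
Accuracy, TNR and FPR as mean (std) over folds, plus the DI count.

AUC uses the rank-statistic definition with ties counted 1/2, i.e.
``P(score+ > score-) + 0.5 P(score+ = score-)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ROC_AUC", "Recall", "Precision", "F1", "Accuracy", "TNR", "FPR")

ALL_TOPICS = "all topics"


def _binarize(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        known = set(np.unique(arr)) - {"DI", "NDI"}
        if known:
            raise ValueError(f"unknown labels {sorted(known)}")
        return (arr == "DI").astype(int)
    return arr.astype(int)


def roc_auc(scores: Sequence[float], labels) -> float:
    """Rank-statistic ROC AUC; ties between classes count one half.

    Raises on single-class input (the statistic is undefined there).
    """
    y = _binarize(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(s)  # average ranks implement the tie = 1/2 convention
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def operating_point(scores: Sequence[float], labels, max_fpr: float = 0.05) -> float:
    """Smallest threshold whose realized FPR is <= ``max_fpr``.

    Predictions are ``score >= threshold``.  A threshold just above the
    top score (FPR = 0) always qualifies, so the function is total for
    two-class inputs.
    """
    y = _binarize(labels)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("operating_point needs both classes present")
    neg = np.sort(s[y == 0])
    n_neg = len(neg)
    for t in np.unique(s):
        fpr = float((neg >= t).sum()) / n_neg
        if fpr <= max_fpr:
            return float(t)
    return float(np.nextafter(s.max(), np.inf))


def confusion_metrics(
    scores: Sequence[float], labels, threshold: float
) -> dict[str, float]:
    """Threshold the scores and compute the Table-style confusion metrics.

    Zero-denominator conventions (no predicted positives, no negatives)
    return 0 with a logged warning instead of raising, so parameter
    sweeps never crash on degenerate slices.
    """
    y = _binarize(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))

    def _ratio(num: int, den: int, what: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator); reporting 0", what)
            return 0.0
        return num / den

    recall = _ratio(tp, tp + fn, "Recall")
    precision = _ratio(tp, tp + fp, "Precision")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "Recall": recall,
        "Precision": precision,
        "F1": f1,
        "Accuracy": (tp + tn) / len(y) if len(y) else 0.0,
        "TNR": _ratio(tn, tn + fp, "TNR"),
        "FPR": _ratio(fp, fp + tn, "FPR"),
    }


@dataclass
class MetricsReport:
    """Per-topic metric battery: mean (std) over folds plus DI counts.

    ``frame`` is indexed by topic (plus an ``"all topics"`` row pooling
    every screening-topic record) with ``<metric>_mean`` / ``<metric>_std``
    columns and ``n_DI``.  ``fold_frame`` keeps the raw per-(topic, fold)
    values, including each fold's chosen threshold.
    """

    frame: pd.DataFrame
    fold_frame: pd.DataFrame
    max_fpr: float

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=True, float_format="%.6f")
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "max_fpr": self.max_fpr,
            "topics": json.loads(self.frame.to_json(orient="index")),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    def __str__(self) -> str:
        lines = [f"Metric battery (operating point: FPR <= {self.max_fpr:g} per fold)"]
        show = self.frame.copy()
        for m in METRIC_NAMES:
            show[m] = [
                f"{mu:.2f} ({sd:.2f})" if np.isfinite(mu) else "n/a"
                for mu, sd in zip(show[f"{m}_mean"], show[f"{m}_std"])
            ]
        cols = list(METRIC_NAMES) + ["n_DI"]
        lines.append(show[cols].to_string())
        return "\n".join(lines)


def per_topic_report(
    oof: pd.DataFrame, max_fpr: float = 0.05
) -> MetricsReport:
    """Build the per-topic report from an OOF screening-topic score table.

    ``oof`` needs columns ``screening_id, topic, fold, score, label``.
    The operating point is chosen independently on each (topic, fold)
    slice — and on each pooled fold for the "all topics" row — so the
    realized FPR obeys the budget slice by slice.  Slices with a single
    class are logged and excluded from that metric's mean/std.
    """
    required = {"screening_id", "topic", "fold", "score", "label"}
    missing = required - set(oof.columns)
    if missing:
        raise ValueError(f"OOF table missing columns {sorted(missing)}")

    topics = sorted(oof["topic"].unique())
    fold_rows: list[dict[str, object]] = []
    for topic in topics + [ALL_TOPICS]:
        sub_all = oof if topic == ALL_TOPICS else oof[oof["topic"] == topic]
        for fold in sorted(sub_all["fold"].unique()):
            sub = sub_all[sub_all["fold"] == fold]
            y = _binarize(sub["label"])
            row: dict[str, object] = {"topic": topic, "fold": int(fold)}
            if y.sum() == 0 or y.sum() == len(y):
                logger.warning(
                    "topic %r fold %s has a single class; metrics unavailable",
                    topic,
                    fold,
                )
                fold_rows.append(row)
                continue
            scores = sub["score"].to_numpy()
            thr = operating_point(scores, y, max_fpr)
            row["threshold"] = thr
            row["ROC_AUC"] = roc_auc(scores, y)
            row.update(confusion_metrics(scores, y, thr))
            row["n_negatives"] = int((y == 0).sum())
            fold_rows.append(row)
    fold_frame = pd.DataFrame(fold_rows)

    rows = {}
    for topic in topics + [ALL_TOPICS]:
        sub = fold_frame[fold_frame["topic"] == topic]
        entry: dict[str, float] = {}
        for m in METRIC_NAMES:
            vals = sub[m].dropna() if m in sub else pd.Series(dtype=float)
            entry[f"{m}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            entry[f"{m}_std"] = float(vals.std(ddof=0)) if len(vals) else float("nan")
        pool = oof if topic == ALL_TOPICS else oof[oof["topic"] == topic]
        entry["n_DI"] = int((_binarize(pool["label"]) == 1).sum())
        rows[topic] = entry
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "topic"
    return MetricsReport(frame=frame, fold_frame=fold_frame, max_fpr=max_fpr)
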