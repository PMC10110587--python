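"""Flagging: rank NDI conclusions most contradicted by the model.

The tool's end product: among conclusions where the examiner found *no*
deception (NDI), select those the model scores highest for DI and queue
them for human quality assurance.  DI-concluded rows are never eligible —
the workflow targets missed deception, the error class that can actually
be validated.

On synthetic cohorts with injected examiner errors, :func:`recovery_report`
measures how strongly flagging enriches for the injected errors relative
to the base error rate among eligible NDI conclusions (enrichment = 1
means flagging is no better than chance).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import TruthRecord, truth_table


@dataclass
class FlagReport:
    """Ranked QA candidates: NDI conclusions the model contradicts most."""

    candidates: pd.DataFrame  # screening_id, topic, score, examiner_label
    rule: str
    created: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    config_hash: str | None = None

    def to_csv(self, path: str | Path) -> Path:
        # numeric artifact: deliberately excludes the timestamp so reruns
        # under an identical config are byte-stable
        path = Path(path)
        self.candidates.to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "rule": self.rule,
            "created": self.created,
            "config_hash": self.config_hash,
            "candidates": self.candidates.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


@dataclass
class RecoveryReport:
    """How well flagging recovered injected examiner errors."""

    k: int
    flagged: int
    hits: int
    precision_at_k: float
    base_rate: float
    enrichment: float
    per_topic: pd.DataFrame

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "k": self.k,
            "flagged": self.flagged,
            "hits": self.hits,
            "precision_at_k": self.precision_at_k,
            "base_rate": self.base_rate,
            "enrichment": self.enrichment,
            "per_topic": self.per_topic.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def _eligible(scores: pd.DataFrame) -> pd.DataFrame:
    required = {"screening_id", "topic", "score", "label"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns {sorted(missing)}")
    if scores["score"].min() < 0 or scores["score"].max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    elig = scores[scores["label"] == "NDI"].copy()
    # deterministic ranking: score desc, then screening_id / topic asc
    return elig.sort_values(
        ["score", "screening_id", "topic"], ascending=[False, True, True], kind="mergesort"
    )


def flag_candidates(
    scores: pd.DataFrame,
    per_topic_k: int | dict[str, int] | None = None,
    threshold: float | None = None,
    top_fraction: float | None = None,
    config_hash: str | None = None,
) -> FlagReport:
    """Select QA candidates among NDI conclusions by model DI score.

    Exactly one selection rule must be given:

    * ``per_topic_k`` — the top-k scored NDI conclusions per topic (an int
      or a per-topic mapping), mirroring a fixed QA budget per topic;
    * ``threshold`` — every NDI conclusion with score >= threshold;
    * ``top_fraction`` — the globally top-scored fraction of all eligible
      NDI conclusions (at least one).

    ``scores`` needs columns ``screening_id, topic, score, label`` where
    ``label`` is the examiner conclusion.
    """
    rules = [per_topic_k is not None, threshold is not None, top_fraction is not None]
    if sum(rules) != 1:
        raise ValueError("give exactly one of per_topic_k, threshold, top_fraction")
    elig = _eligible(scores)

    if threshold is not None:
        if not (0.0 <= threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")
        sel = elig[elig["score"] >= threshold]
        rule = f"threshold>={threshold:g}"
    elif top_fraction is not None:
        if not (0.0 < top_fraction <= 1.0):
            raise ValueError("top_fraction must lie in (0, 1]")
        k_total = max(1, int(round(top_fraction * len(elig))))
        sel = elig.head(k_total)
        rule = f"top_fraction={top_fraction:g}"
    else:
        if isinstance(per_topic_k, int):
            if per_topic_k < 0:
                raise ValueError("per_topic_k must be >= 0")
            kmap = {t: per_topic_k for t in elig["topic"].unique()}
        else:
            assert per_topic_k is not None
            if any(k < 0 for k in per_topic_k.values()):
                raise ValueError("per_topic_k values must be >= 0")
            kmap = dict(per_topic_k)
        parts = [
            grp.head(kmap.get(topic, 0)) for topic, grp in elig.groupby("topic", sort=True)
        ]
        sel = pd.concat(parts) if parts else elig.iloc[:0]
        # keep within-topic ordering but present topics alphabetically
        sel = sel.sort_values(
            ["topic", "score", "screening_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        rule = f"per_topic_k={per_topic_k!r}"

    out = sel[["screening_id", "topic", "score"]].copy()
    out["examiner_label"] = "NDI"
    return FlagReport(candidates=out.reset_index(drop=True), rule=rule, config_hash=config_hash)


def chance_flags(
    scores: pd.DataFrame, k_total: int, rng: np.random.Generator
) -> FlagReport:
    """Baseline: ``k_total`` eligible NDI conclusions drawn uniformly."""
    elig = _eligible(scores)
    k = min(k_total, len(elig))
    idx = rng.choice(len(elig), size=k, replace=False)
    sel = elig.iloc[np.sort(idx)]
    out = sel[["screening_id", "topic", "score"]].copy()
    out["examiner_label"] = "NDI"
    return FlagReport(candidates=out.reset_index(drop=True), rule=f"chance k={k_total}")


def recovery_report(
    flags: FlagReport, truths: Sequence[TruthRecord]
) -> RecoveryReport:
    """Score a flag report against injected examiner errors.

    Precision@k counts flagged conclusions whose label was an injected
    error; enrichment divides it by the base error rate among *all*
    eligible (NDI-labeled) conclusions.  Both are 0 when no errors were
    injected.
    """
    tt = truth_table(truths)
    cand = flags.candidates
    merged = cand.merge(tt, on=["screening_id", "topic"], how="left", indicator=True)
    if (merged["_merge"] != "both").any():
        missing = merged.loc[merged["_merge"] != "both", ["screening_id", "topic"]]
        raise ValueError(
            f"truth records missing for flagged conclusions: {missing.to_dict('records')}"
        )

    elig = tt[tt["examiner_label"] == "NDI"]
    n_elig = len(elig)
    n_errors = int(elig["injected_error"].sum())
    base_rate = n_errors / n_elig if n_elig else 0.0

    k = len(cand)
    hits = int(merged["injected_error"].sum())
    precision = hits / k if k else 0.0
    enrichment = precision / base_rate if base_rate > 0 else 0.0

    per_topic = (
        merged.groupby("topic")
        .agg(flagged=("injected_error", "size"), hits=("injected_error", "sum"))
        .reset_index()
    )
    per_topic["hits"] = per_topic["hits"].astype(int)
    return RecoveryReport(
        k=k,
        flagged=k,
        hits=hits,
        precision_at_k=precision,
        base_rate=base_rate,
        enrichment=enrichment,
        per_topic=per_topic,
    )
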