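"""Two-level stacking models for second-opinion scoring of screenings.

The estimator follows the statsmodels convention: a model object is built
from data, ``fit()`` returns a results object carrying out-of-fold (OOF)
scores, fitted per-fold learners, diagnostics and a ``summary()``.

Architecture (identical for every variant):

* folds are assigned at screening level (group key = screening_id) with
  greedy label stratification, so no screening's rows ever span folds;
* a first-level gradient-boosted classifier is trained per fold on the
  600 physiological features of one row per (screening, test, topic) and
  produces an OOF DI probability for each test row;
* per (screening, topic) the per-test OOF probabilities are reduced to
  ``pred_proba_min/max/mean/diff`` and concatenated with whitelisted
  covariates (age, sex, job fields, examiner id, weather, geomagnetic
  index); a second-level classifier per fold turns these into the final
  screening-topic DI probability, again out of fold.

Variants: *basic* (topic-blind), *one-topic* (both levels train on a
single topic's rows but score any topic), *random-forest* (the basic
architecture with random forests, depth 5), and the *universal* ensemble
— the arithmetic mean of the confidences of a basic gradient-boosting
model with covariates, a one-topic model with covariates, and a basic
random-forest model.

Class imbalance (DI prevalence is a small minority) is handled by
balanced class weights at every level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier

from . import metrics as _metrics
from .features import (
    FeaturizeConfig,
    build_feature_table,
    feature_columns,
    meta_features,
)
from .ncca import Screening

#: Covariate fields taken from the screening header.
SUBJECT_FIELDS = (
    "subject_age",
    "subject_sex",
    "subject_type",
    "current_position",
    "current_department",
    "accepted_position",
    "accepted_department",
)

#: Covariate fields taken from the alternative-data table.
ALT_TABLE_FIELDS = (
    "examiner_id",
    "geomagnetic_index",
    "Temperature",
    "Pressure",
    "Humidity",
    "Wind",
    "Wind speed",
    "Dew Point",
    "Condition",
    "Time",
)

ALT_FIELDS_ALL = SUBJECT_FIELDS + ALT_TABLE_FIELDS

_CATEGORICAL_FIELDS = {
    "subject_sex",
    "subject_type",
    "current_position",
    "current_department",
    "accepted_position",
    "accepted_department",
    "examiner_id",
    "Condition",
    "topic",
    "topic_code",
}

_DEFAULT_GBM = dict(
    n_estimators=100,
    learning_rate=0.08,
    num_leaves=31,
    min_child_samples=10,
    max_bin=63,
    feature_fraction=0.5,
    class_weight="balanced",
    deterministic=True,
    force_col_wise=True,
    n_jobs=1,
    verbosity=-1,
)

_DEFAULT_GBM_SECOND = dict(
    n_estimators=120,
    learning_rate=0.08,
    num_leaves=15,
    min_child_samples=10,
    max_bin=63,
    class_weight="balanced",
    deterministic=True,
    force_col_wise=True,
    n_jobs=1,
    verbosity=-1,
)

_DEFAULT_RF = dict(
    n_estimators=100,
    max_depth=5,
    class_weight="balanced",
    n_jobs=1,
)


@dataclass
class TrainConfig:
    """Training configuration shared by all model variants."""

    k_folds: int = 5
    seed: int = 0
    first_level: dict = field(default_factory=lambda: dict(_DEFAULT_GBM))
    second_level: dict = field(default_factory=lambda: dict(_DEFAULT_GBM_SECOND))
    rf: dict = field(default_factory=lambda: dict(_DEFAULT_RF))
    alt_fields: tuple[str, ...] = ("subject_age", "subject_sex")
    topic_filter: str | None = None
    exclude_topics: tuple[str, ...] = ()
    topic_as_feature: bool = False

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        unknown = set(self.alt_fields) - set(ALT_FIELDS_ALL)
        if unknown:
            raise ValueError(f"unknown alt-data fields {sorted(unknown)}")


@dataclass
class FoldAssignment:
    """Screening-level group fold map: screening_id -> fold in [0, k)."""

    assignment: dict[str, int]
    k: int

    def fold_of(self, screening_id: str) -> int:
        return self.assignment[screening_id]

    def __contains__(self, screening_id: str) -> bool:
        return screening_id in self.assignment

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["screening_id", "fold"]
        )


def make_group_folds(rows: pd.DataFrame, k: int, seed: int) -> FoldAssignment:
    """Stratified group K-fold at screening level.

    Groups (screenings) are shuffled by ``seed``, stably sorted by their
    any-topic DI label, and dealt round-robin, which balances fold sizes
    to within one screening and spreads positives evenly.  Deterministic
    given (rows, k, seed).
    """
    if "screening_id" not in rows or "label" not in rows:
        raise ValueError("rows need screening_id and label columns")
    labels = (
        rows.assign(_y=_metrics._binarize(rows["label"]))
        .groupby("screening_id")["_y"]
        .max()
        .sort_index()
    )
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the number of screenings ({len(labels)})")
    if int(labels.sum()) == 0:
        raise ValueError("no positive (DI) screening in the data")
    rng = np.random.default_rng(seed)
    sids = labels.index.to_numpy()
    order = rng.permutation(len(sids))
    shuffled = sids[order]
    shuffled_labels = labels.to_numpy()[order]
    # stable sort: positives first, ties keep the shuffled order
    rank = np.argsort(-shuffled_labels, kind="mergesort")
    assignment = {str(shuffled[i]): int(j % k) for j, i in enumerate(rank)}
    return FoldAssignment(assignment=assignment, k=k)


def score_universal(s_basic_alt, s_onetopic_alt, s_rf_basic):
    """Confidence averaging of the three ensemble members (elementwise)."""
    arrs = [np.asarray(s, dtype=float) for s in (s_basic_alt, s_onetopic_alt, s_rf_basic)]
    for a in arrs:
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("scores must lie in [0, 1]")
    out = (arrs[0] + arrs[1] + arrs[2]) / 3.0
    return float(out) if np.isscalar(s_basic_alt) or out.ndim == 0 else out


# --- covariates -----------------------------------------------------------


def screening_covariates(
    screenings: Sequence[Screening], alt: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-screening covariate table: header fields joined with alt data."""
    rows = [{"screening_id": s.screening_id, **{f: getattr(s, f) for f in SUBJECT_FIELDS}}
            for s in screenings]
    cov = pd.DataFrame(rows)
    if alt is not None:
        cov = cov.merge(alt, on="screening_id", how="left")
    return cov.set_index("screening_id").sort_index()


_sanitize_re = re.compile(r"[^0-9A-Za-z_]")


def _sanitize_columns(df: pd.DataFrame) -> pd.DataFrame:
    # LightGBM rejects feature names with spaces or JSON special characters
    return df.rename(columns=lambda c: _sanitize_re.sub("_", str(c)))


def _prepare_design(
    df: pd.DataFrame, categories: dict[str, list] | None = None
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Cast declared categorical fields to pandas category dtype.

    Categories are frozen at fit time; unseen values at predict time fall
    into an explicit unknown bucket.
    """
    out = df.copy()
    cats: dict[str, list] = {}
    for col in out.columns:
        if col in _CATEGORICAL_FIELDS or out[col].dtype == object:
            if categories is None:
                levels = sorted(map(str, out[col].dropna().unique())) + ["__unseen__"]
            else:
                levels = categories[col]
            vals = out[col].astype(str).where(out[col].notna(), None)
            vals = vals.where(vals.isin(levels), "__unseen__")
            out[col] = pd.Categorical(vals, categories=levels)
            cats[col] = levels
    return out, cats


def _one_hot(df: pd.DataFrame) -> pd.DataFrame:
    cat_cols = [c for c in df.columns if isinstance(df[c].dtype, pd.CategoricalDtype)]
    return pd.get_dummies(df, columns=cat_cols, dtype=float)


@dataclass
class _FoldModels:
    first: object
    second: object
    second_categories: dict[str, list]
    second_columns: list[str]


# --- the model ------------------------------------------------------------


class SecondOpinionModel:
    """Two-level stacking model over 600-feature rows.

    Parameters
    ----------
    rows
        Feature table from :func:`polyverify.features.build_feature_table`
        (columns ``screening_id, test_index, topic, label`` + 600 features).
    covariates
        Per-screening covariate table from :func:`screening_covariates`
        (optional; required when ``config.alt_fields`` is non-empty).
    config
        :class:`TrainConfig`.
    variant
        ``"basic"`` (topic-blind boosting), ``"one_topic"`` (training rows
        of both levels filtered to ``config.topic_filter``), or
        ``"random_forest"`` (basic architecture, random-forest learners).
    """

    def __init__(
        self,
        rows: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        config: TrainConfig | None = None,
        variant: str = "basic",
    ):
        if variant not in ("basic", "one_topic", "random_forest"):
            raise ValueError(f"unknown variant {variant!r}")
        config = config or TrainConfig()
        config.validate()
        if variant == "one_topic" and not config.topic_filter:
            raise ValueError("one_topic variant requires config.topic_filter")
        if rows.empty:
            raise ValueError("empty feature table")
        if config.alt_fields and covariates is None:
            raise ValueError("alt_fields requested but no covariates supplied")
        if covariates is not None:
            missing = set(config.alt_fields) - set(covariates.columns)
            if missing:
                raise ValueError(f"covariates missing fields {sorted(missing)}")
        if variant == "one_topic" and config.topic_filter not in set(rows["topic"]):
            raise ValueError(f"topic {config.topic_filter!r} absent from the data")
        self.rows = rows.reset_index(drop=True)
        self.covariates = covariates
        self.config = config
        self.variant = variant
        self.feature_cols = feature_columns(rows)

    @classmethod
    def from_cohort(
        cls,
        screenings: Sequence[Screening],
        alt: pd.DataFrame | None = None,
        config: TrainConfig | None = None,
        variant: str = "basic",
        featurize_config: FeaturizeConfig | None = None,
    ) -> "SecondOpinionModel":
        rows = build_feature_table(screenings, featurize_config)
        cov = screening_covariates(screenings, alt)
        return cls(rows, cov, config=config, variant=variant)

    # -- learners ----------------------------------------------------------

    def _make_first(self, fold: int):
        if self.variant == "random_forest":
            return RandomForestClassifier(
                random_state=self.config.seed + 1000 + fold, **self.config.rf
            )
        return LGBMClassifier(
            random_state=self.config.seed + 1000 + fold, **self.config.first_level
        )

    def _make_second(self, fold: int):
        if self.variant == "random_forest":
            return RandomForestClassifier(
                random_state=self.config.seed + 2000 + fold, **self.config.rf
            )
        return LGBMClassifier(
            random_state=self.config.seed + 2000 + fold, **self.config.second_level
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, folds: FoldAssignment | None = None) -> "SecondOpinionResults":
        cfg = self.config
        rows = self.rows
        if folds is None:
            folds = make_group_folds(rows, cfg.k_folds, cfg.seed)
        fold_col = rows["screening_id"].map(folds.assignment)
        if fold_col.isna().any():
            raise ValueError("fold assignment does not cover every screening")
        y_all = _metrics._binarize(rows["label"])
        X_all = rows[self.feature_cols]

        def _train_mask(in_fold: pd.Series) -> pd.Series:
            mask = ~in_fold
            if cfg.exclude_topics:
                mask &= ~rows["topic"].isin(cfg.exclude_topics)
            if self.variant == "one_topic":
                mask &= rows["topic"] == cfg.topic_filter
            return mask

        oof_test = np.full(len(rows), np.nan)
        first_models: list[object] = []
        for f in range(folds.k):
            in_fold = fold_col == f
            tr = _train_mask(in_fold)
            ytr = y_all[tr.to_numpy()]
            if ytr.min() == ytr.max():
                raise ValueError(
                    f"single-class first-level training split in fold {f}"
                )
            clf = self._make_first(f)
            clf.fit(X_all[tr.to_numpy()], ytr)
            first_models.append(clf)
            oof_test[in_fold.to_numpy()] = clf.predict_proba(
                X_all[in_fold.to_numpy()]
            )[:, 1]

        oof_test_scores = rows[["screening_id", "test_index", "topic", "label"]].copy()
        oof_test_scores["fold"] = fold_col.to_numpy()
        oof_test_scores["score"] = oof_test

        meta = self._meta_table(oof_test_scores)
        meta_X_cols = [c for c in meta.columns if c not in ("screening_id", "topic", "label", "fold")]

        oof_meta = np.full(len(meta), np.nan)
        fold_models: list[_FoldModels] = []
        meta_fold = meta["fold"].to_numpy()
        y_meta = _metrics._binarize(meta["label"])
        for f in range(folds.k):
            in_fold = meta_fold == f
            tr = ~in_fold
            if cfg.exclude_topics:
                tr &= ~meta["topic"].isin(cfg.exclude_topics).to_numpy()
            if self.variant == "one_topic":
                tr &= (meta["topic"] == cfg.topic_filter).to_numpy()
            ytr = y_meta[tr]
            if len(ytr) == 0 or ytr.min() == ytr.max():
                raise ValueError(
                    f"single-class second-level training split in fold {f}"
                )
            Xtr_raw = meta.loc[tr, meta_X_cols]
            Xtr, cats = _prepare_design(Xtr_raw)
            Xtr = _sanitize_columns(Xtr)
            clf = self._make_second(f)
            if self.variant == "random_forest":
                Xtr_enc = _one_hot(Xtr)
                clf.fit(Xtr_enc, ytr)
                cols = list(Xtr_enc.columns)
            else:
                clf.fit(Xtr, ytr)
                cols = list(Xtr.columns)
            fold_models.append(
                _FoldModels(first_models[f], clf, cats, cols)
            )
            Xva, _ = _prepare_design(meta.loc[in_fold, meta_X_cols], cats)
            Xva = _sanitize_columns(Xva)
            if self.variant == "random_forest":
                Xva = _one_hot(Xva).reindex(columns=cols, fill_value=0.0)
            oof_meta[in_fold] = clf.predict_proba(Xva)[:, 1]

        oof_scores = meta[["screening_id", "topic", "label"]].copy()
        oof_scores["fold"] = meta_fold
        oof_scores["score"] = oof_meta

        return SecondOpinionResults(
            model=self,
            folds=folds,
            fold_models=fold_models,
            oof_test_scores=oof_test_scores,
            oof_scores=oof_scores,
        )

    def _meta_table(self, test_scores: pd.DataFrame) -> pd.DataFrame:
        """Aggregate per-test scores to the second-level design table."""
        cfg = self.config
        recs = []
        grouped = test_scores.sort_values(["screening_id", "topic", "test_index"]).groupby(
            ["screening_id", "topic"], sort=True
        )
        for (sid, topic), grp in grouped:
            rec = {
                "screening_id": sid,
                "topic": topic,
                "label": grp["label"].iloc[0],
                "fold": int(grp["fold"].iloc[0]),
            }
            rec.update(meta_features(grp["score"].to_numpy()))
            recs.append(rec)
        meta = pd.DataFrame(recs)
        if cfg.alt_fields:
            cov = self.covariates[list(cfg.alt_fields)]
            meta = meta.merge(cov, left_on="screening_id", right_index=True, how="left")
        if cfg.topic_as_feature:
            meta["topic_code"] = meta["topic"]
        return meta


class SecondOpinionResults:
    """Fitted two-level stacking model: OOF scores, learners, diagnostics."""

    def __init__(
        self,
        model: SecondOpinionModel,
        folds: FoldAssignment,
        fold_models: list[_FoldModels],
        oof_test_scores: pd.DataFrame,
        oof_scores: pd.DataFrame,
    ):
        self.model = model
        self.config = model.config
        self.variant = model.variant
        self.folds = folds
        self.fold_models = fold_models
        self.oof_test_scores = oof_test_scores
        self.oof_scores = oof_scores

    # -- diagnostics -------------------------------------------------------

    @property
    def oof_auc(self) -> float:
        """Pooled OOF screening-topic ROC AUC."""
        return _metrics.roc_auc(self.oof_scores["score"], self.oof_scores["label"])

    @property
    def oof_test_auc(self) -> float:
        """Pooled OOF first-level (per-test row) ROC AUC."""
        return _metrics.roc_auc(
            self.oof_test_scores["score"], self.oof_test_scores["label"]
        )

    def metrics_report(self, max_fpr: float = 0.05) -> _metrics.MetricsReport:
        return _metrics.per_topic_report(self.oof_scores, max_fpr=max_fpr)

    def summary(self) -> str:
        cfg = self.config
        n_scr = len(self.folds.assignment)
        lines = [
            "Second-opinion stacking model",
            "=" * 64,
            f"variant:            {self.variant}"
            + (f" (topic={cfg.topic_filter})" if self.variant == "one_topic" else ""),
            f"screenings:         {n_scr}",
            f"test rows:          {len(self.oof_test_scores)}",
            f"screening-topics:   {len(self.oof_scores)}",
            f"folds:              {self.folds.k} (group = screening, stratified)",
            f"covariates:         {', '.join(cfg.alt_fields) or 'none'}",
            f"excluded topics:    {', '.join(cfg.exclude_topics) or 'none'}",
            f"OOF AUC (tests):    {self.oof_test_auc:.4f}",
            f"OOF AUC (topics):   {self.oof_auc:.4f}",
            "-" * 64,
            "per-topic OOF AUC:",
        ]
        for topic, grp in self.oof_scores.groupby("topic"):
            y = _metrics._binarize(grp["label"])
            if 0 < y.sum() < len(y):
                lines.append(
                    f"  {topic:<24s} {_metrics.roc_auc(grp['score'], y):.4f}"
                    f"  (n_DI={int(y.sum())})"
                )
            else:
                lines.append(f"  {topic:<24s} n/a (single class)")
        return "\n".join(lines)

    def plot_scores(self, topic: str | None = None, ax=None):
        """Histogram of OOF scores split by examiner conclusion."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.oof_scores
        if topic is not None:
            sub = sub[sub["topic"] == topic]
        for label, color in (("NDI", "tab:blue"), ("DI", "tab:red")):
            vals = sub.loc[sub["label"] == label, "score"]
            ax.hist(vals, bins=30, range=(0, 1), alpha=0.6, label=label, color=color)
        ax.set_xlabel("model DI probability")
        ax.set_ylabel("conclusions")
        ax.set_title(topic or "all topics")
        ax.legend()
        return ax

    # -- prediction --------------------------------------------------------

    def predict(
        self,
        screening: Screening | None = None,
        rows: pd.DataFrame | None = None,
        covariates: pd.DataFrame | None = None,
        featurize_config: FeaturizeConfig | None = None,
    ) -> pd.DataFrame:
        """Score screening-topics: columns ``screening_id, topic, score``.

        Screenings that took part in training are returned their stored
        OOF score (leak guard); unseen screenings are scored with all K
        fold chains and the scores averaged.
        """
        if (screening is None) == (rows is None):
            raise ValueError("pass exactly one of screening= or rows=")
        if screening is not None:
            rows = build_feature_table([screening], featurize_config)
            if rows.empty:
                raise ValueError(
                    f"screening {screening.screening_id} has no featurizable rows"
                )
            if covariates is None and self.config.alt_fields:
                covariates = screening_covariates([screening])
        assert rows is not None

        seen = rows["screening_id"].isin(self.folds.assignment)
        out_parts: list[pd.DataFrame] = []
        if seen.any():
            ids = rows.loc[seen, "screening_id"].unique()
            stored = self.oof_scores[self.oof_scores["screening_id"].isin(ids)]
            out_parts.append(stored[["screening_id", "topic", "score"]])
        if (~seen).any():
            out_parts.append(self._predict_unseen(rows[~seen], covariates))
        out = pd.concat(out_parts, ignore_index=True)
        return out.sort_values(["screening_id", "topic"]).reset_index(drop=True)

    def _predict_unseen(
        self, rows: pd.DataFrame, covariates: pd.DataFrame | None
    ) -> pd.DataFrame:
        cfg = self.config
        if cfg.alt_fields:
            if covariates is None:
                raise ValueError("covariates required for alt-data fields")
            missing = set(cfg.alt_fields) - set(covariates.columns)
            if missing:
                raise ValueError(f"covariates missing fields {sorted(missing)}")
        X = rows[self.model.feature_cols]
        per_fold_scores: list[np.ndarray] = []
        for f, fm in enumerate(self.fold_models):
            test_scores = rows[["screening_id", "test_index", "topic"]].copy()
            test_scores["score"] = fm.first.predict_proba(X)[:, 1]  # type: ignore[attr-defined]
            recs = []
            grouped = test_scores.sort_values(
                ["screening_id", "topic", "test_index"]
            ).groupby(["screening_id", "topic"], sort=True)
            for (sid, topic), grp in grouped:
                rec = {"screening_id": sid, "topic": topic}
                rec.update(meta_features(grp["score"].to_numpy()))
                recs.append(rec)
            meta = pd.DataFrame(recs)
            if cfg.alt_fields:
                meta = meta.merge(
                    covariates[list(cfg.alt_fields)],
                    left_on="screening_id",
                    right_index=True,
                    how="left",
                )
            if cfg.topic_as_feature:
                meta["topic_code"] = meta["topic"]
            Xm_cols = [c for c in meta.columns if c not in ("screening_id", "topic")]
            Xm, _ = _prepare_design(meta[Xm_cols], fm.second_categories)
            Xm = _sanitize_columns(Xm)
            if self.variant == "random_forest":
                Xm = _one_hot(Xm).reindex(columns=fm.second_columns, fill_value=0.0)
            else:
                Xm = Xm.reindex(columns=fm.second_columns)
            per_fold_scores.append(fm.second.predict_proba(Xm)[:, 1])  # type: ignore[attr-defined]
        keys = meta[["screening_id", "topic"]].copy()
        keys["score"] = np.mean(per_fold_scores, axis=0)
        return keys

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(
            {
                "config": self.config,
                "variant": self.variant,
                "folds": self.folds,
                "fold_models": self.fold_models,
                "feature_cols": self.model.feature_cols,
            },
            directory / "bundle.joblib",
        )
        self.oof_test_scores.to_csv(directory / "oof_test_scores.csv", index=False)
        self.oof_scores.to_csv(directory / "oof_scores.csv", index=False)
        return directory


# --- functional surface ---------------------------------------------------


def train_two_level(
    rows: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    folds: FoldAssignment | None = None,
    config: TrainConfig | None = None,
) -> SecondOpinionResults:
    """Train the basic (topic-blind) two-level stacking model."""
    return SecondOpinionModel(rows, covariates, config=config, variant="basic").fit(folds)


def train_one_topic(
    rows: pd.DataFrame,
    topic: str,
    covariates: pd.DataFrame | None = None,
    folds: FoldAssignment | None = None,
    config: TrainConfig | None = None,
) -> SecondOpinionResults:
    """Train a model whose training data is filtered to one topic."""
    config = replace(config, topic_filter=topic) if config else TrainConfig(topic_filter=topic)
    return SecondOpinionModel(rows, covariates, config=config, variant="one_topic").fit(folds)


class UniversalModel:
    """Confidence-averaging ensemble of three basic-architecture members.

    Members: (1) basic gradient boosting with covariates, (2) a one-topic
    gradient-boosting model with covariates anchored on ``anchor_topic``,
    (3) a basic random forest.  All members share one fold assignment, so
    the averaged OOF score of a screening-topic is still out of fold.
    """

    def __init__(
        self,
        rows: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        config: TrainConfig | None = None,
        anchor_topic: str = "drug_abuse",
        alt_fields: tuple[str, ...] = ALT_FIELDS_ALL,
    ):
        self.rows = rows
        self.covariates = covariates
        base = config or TrainConfig()
        self.anchor_topic = anchor_topic
        self.config_basic = replace(base, alt_fields=tuple(alt_fields))
        self.config_one = replace(
            base, alt_fields=tuple(alt_fields), topic_filter=anchor_topic
        )
        self.config_rf = base

    def fit(self, folds: FoldAssignment | None = None) -> "UniversalResults":
        if folds is None:
            folds = make_group_folds(
                self.rows, self.config_basic.k_folds, self.config_basic.seed
            )
        basic = SecondOpinionModel(
            self.rows, self.covariates, self.config_basic, variant="basic"
        ).fit(folds)
        one = SecondOpinionModel(
            self.rows, self.covariates, self.config_one, variant="one_topic"
        ).fit(folds)
        rf = SecondOpinionModel(
            self.rows, self.covariates, self.config_rf, variant="random_forest"
        ).fit(folds)
        return UniversalResults(self, folds, basic, one, rf)


class UniversalResults:
    """Fitted universal ensemble: member results plus averaged OOF scores."""

    def __init__(
        self,
        model: UniversalModel,
        folds: FoldAssignment,
        basic: SecondOpinionResults,
        one_topic: SecondOpinionResults,
        rf: SecondOpinionResults,
    ):
        self.model = model
        self.folds = folds
        self.members = {"basic_alt": basic, "one_topic_alt": one_topic, "rf_basic": rf}
        key = ["screening_id", "topic"]
        merged = (
            basic.oof_scores.rename(columns={"score": "s_basic"})
            .merge(
                one_topic.oof_scores[key + ["score"]].rename(columns={"score": "s_one"}),
                on=key,
            )
            .merge(
                rf.oof_scores[key + ["score"]].rename(columns={"score": "s_rf"}),
                on=key,
            )
        )
        merged["score"] = score_universal(
            merged["s_basic"].to_numpy(),
            merged["s_one"].to_numpy(),
            merged["s_rf"].to_numpy(),
        )
        self.oof_scores = merged[key + ["label", "fold", "score"]]

    @property
    def oof_auc(self) -> float:
        return _metrics.roc_auc(self.oof_scores["score"], self.oof_scores["label"])

    def metrics_report(self, max_fpr: float = 0.05) -> _metrics.MetricsReport:
        return _metrics.per_topic_report(self.oof_scores, max_fpr=max_fpr)

    def predict(self, **kwargs) -> pd.DataFrame:
        parts = [m.predict(**kwargs) for m in self.members.values()]
        out = parts[0][["screening_id", "topic"]].copy()
        out["score"] = score_universal(
            parts[0]["score"].to_numpy(),
            parts[1]["score"].to_numpy(),
            parts[2]["score"].to_numpy(),
        )
        return out

    def summary(self) -> str:
        lines = [
            "Universal second-opinion ensemble (confidence averaging)",
            "=" * 64,
            f"anchor one-topic member: {self.model.anchor_topic}",
            f"OOF AUC (ensemble):      {self.oof_auc:.4f}",
            "member OOF AUCs:",
        ]
        for name, res in self.members.items():
            lines.append(f"  {name:<16s} {res.oof_auc:.4f}")
        return "\n".join(lines)
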