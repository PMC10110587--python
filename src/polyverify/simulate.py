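"""Synthetic screening cohorts with known deception ground truth.

The simulator stands in for a proprietary archive of field screenings: it
produces full recordings in the :mod:`polyverify.ncca` domain model, a
truth table saying which (subject, topic) pairs are actually deceptive,
examiner conclusions corrupted at a controlled error rate, and an
alternative-data table (weather, geomagnetic index, examiner id).

Signal model, per channel::

    x(t) = baseline + slow drift + periodic component + AR(1) noise
           + sum over question events of  A_event * kernel(t - t_start)

The response kernel is a gamma-shaped rise–decay starting 0.5 s after
question onset with an 8 s support — a generic stimulus-locked response,
not a physiological model; units are arbitrary.  The event amplitude is::

    A_event = gain_channel * R_subject,channel * jitter_event * (1 + delta)

where the ``(1 + delta)`` factor applies only to relevant questions of
topics on which the subject is truly deceptive (``delta`` is the
configured effect size).  ``R`` is a log-normal per-subject reactivity
with a component shared across channels and a per-channel component, so
that between-subject amplitude variation — the main obstacle the
classifier has to overcome — is controlled explicitly.

Deception acts at (subject, topic) level and is constant across tests;
an optional per-test dropout probability emulates subjects who do not
express deception in every test.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import gamma as _gamma_dist

from .ncca import (
    DEFAULT_CHANNELS,
    QuestionEvent,
    Screening,
    SignalChannel,
    write_screening,
)

#: The seven labeled screening topics.
TOPICS = (
    "drug_abuse",
    "corruption",
    "confidential_info_leak",
    "debt",
    "unreported_income",
    "criminal_history",
    "ird_violation",
)


@dataclass(frozen=True)
class ChannelSpec:
    """Static per-channel signal parameters (arbitrary units).

    ``noise_sd`` is the *stationary* standard deviation of the AR(1)
    component; ``kernel_gain`` is signed (electrodermal activity rises on a
    stimulus, peripheral blood volume drops).
    """

    baseline: float
    drift_amp: float
    periodic_freq_hz: float
    periodic_amp: float
    noise_sd: float
    kernel_gain: float


# Gains/SDs chosen once so that a single event response is clearly visible
# above the in-window noise while between-subject reactivity (not sample
# noise) limits separability; see docs/methods.md.
CHANNEL_MODEL: dict[str, ChannelSpec] = {
    "THORACIC_RESP": ChannelSpec(0.0, 0.3, 0.27, 1.0, 0.15, -0.45),
    "ABDOMINAL_RESP": ChannelSpec(0.0, 0.3, 0.23, 0.9, 0.15, -0.40),
    "EDA": ChannelSpec(2.0, 0.5, 0.05, 0.2, 0.25, 1.00),
    "TONIC_EDA": ChannelSpec(2.0, 0.6, 0.01, 0.3, 0.10, 0.50),
    "PLE": ChannelSpec(0.0, 0.2, 1.15, 0.8, 0.15, -0.50),
    "ABS_BLOOD_VOLUME": ChannelSpec(1.0, 0.3, 1.15, 0.3, 0.20, -0.70),
    "HEART_RATE": ChannelSpec(70.0, 2.0, 0.10, 1.5, 1.00, 4.00),
    "CARDIO": ChannelSpec(0.0, 0.3, 1.15, 0.6, 0.20, 0.50),
    "TREMOR": ChannelSpec(0.0, 0.1, 8.00, 0.2, 0.30, 0.30),
    "OPTIONAL": ChannelSpec(0.0, 0.2, 0.50, 0.3, 0.20, 0.40),
}

_POSITIONS = ("clerk", "manager", "senior_manager", "analyst", "cashier", "security")
_DEPARTMENTS = ("retail", "corporate", "it", "treasury", "compliance")
_CONDITIONS = ("clear", "cloudy", "overcast", "rain", "snow")


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the field archive this generator stands in for: seven
    labeled topics, three tests per screening, a 31 Hz device, and a
    minority DI prevalence below 7 %.
    """

    n_screenings: int = 100
    topics: tuple[str, ...] = TOPICS
    tests_per_screening: int = 3
    questions_per_topic_per_test: int = 2
    repetitions_per_question: int = 2
    deception_prevalence: float = 0.06
    effect_size: float = 1.0
    examiner_error_rate: float = 0.0
    error_mode: str = "symmetric"  # or "ndi_only": only true-DI -> NDI flips
    ar_coeff: float = 0.95
    noise_scale: float = 1.0
    subject_sigma: float = 0.30  # log-SD of reactivity shared across channels
    channel_sigma: float = 0.30  # log-SD of the per-channel reactivity part
    event_sigma: float = 0.25  # log-SD of per-event amplitude jitter
    per_test_dropout: float = 0.0
    sampling_rate_hz: float = 31.0
    city: str = "Moscow"
    n_examiners: int = 8
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.deception_prevalence <= 1.0):
            raise ValueError("deception_prevalence must be in [0, 1]")
        if not (0.0 <= self.examiner_error_rate <= 1.0):
            raise ValueError("examiner_error_rate must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.error_mode not in ("symmetric", "ndi_only"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")
        if not (0.0 <= self.per_test_dropout <= 1.0):
            raise ValueError("per_test_dropout must be in [0, 1]")
        if min(
            self.n_screenings,
            self.tests_per_screening,
            self.questions_per_topic_per_test,
            self.repetitions_per_question,
            len(self.topics),
        ) < 1:
            raise ValueError("counts must all be >= 1")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ValueError("ar_coeff must be in [0, 1)")
        unknown = set(self.topics) - set(TOPICS)
        if unknown:
            raise ValueError(f"unknown topics {sorted(unknown)}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")


@dataclass
class TopicTruth:
    true_deceptive: bool
    examiner_label: str  # "DI" or "NDI"
    injected_error: bool = False


@dataclass
class TruthRecord:
    """Ground truth and (possibly corrupted) examiner labels, per topic."""

    screening_id: str
    topics: dict[str, TopicTruth] = field(default_factory=dict)


def truth_table(truths: Iterable[TruthRecord]) -> pd.DataFrame:
    """Long-format truth table: one row per (screening, topic)."""
    rows = [
        {
            "screening_id": t.screening_id,
            "topic": topic,
            "true_deceptive": tt.true_deceptive,
            "examiner_label": tt.examiner_label,
            "injected_error": tt.injected_error,
        }
        for t in truths
        for topic, tt in sorted(t.topics.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "screening_id",
            "topic",
            "true_deceptive",
            "examiner_label",
            "injected_error",
        ],
    )


def response_kernel(
    rate_hz: float,
    delay_s: float = 0.5,
    duration_s: float = 8.0,
    shape: float = 2.0,
    scale_s: float = 1.2,
) -> np.ndarray:
    """Peak-normalized gamma-shaped rise–decay response, sampled at ``rate_hz``.

    Zero during the initial ``delay_s``; support truncated at
    ``delay_s + duration_s``.
    """
    n = int(round((delay_s + duration_s) * rate_hz))
    t = np.arange(n) / rate_hz
    k = _gamma_dist.pdf(t - delay_s, a=shape, scale=scale_s)
    k[t < delay_s] = 0.0
    peak = k.max()
    return k / peak if peak > 0 else k


# --- event schedule -------------------------------------------------------

_SETTLE_S = 20.0
_INTERTEST_GAP_S = 30.0
_TAIL_S = 15.0
_POST_WINDOW_GUARD_S = 6.0  # leaves room for the 5 s post-answer window


def _build_schedule(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[QuestionEvent], float]:
    """Lay out questions on the time axis; return (events, total duration)."""
    events: list[QuestionEvent] = []
    t = _SETTLE_S
    abbrev = {topic: f"{topic[:4].upper()}" for topic in config.topics}
    for test in range(config.tests_per_screening):
        for rep in range(config.repetitions_per_question):
            block: list[tuple[str, str, str | None]] = [
                ("N1", "neutral", None),
                ("C1", "comparison", None),
            ]
            for topic in config.topics:
                for q in range(config.questions_per_topic_per_test):
                    block.append((f"{abbrev[topic]}{q + 1}", "relevant", topic))
            for qid, qtype, topic in block:
                q_dur = rng.uniform(2.0, 3.5)
                ans_delay = rng.uniform(0.8, 2.0)
                t_end = t + q_dur
                t_ans = t_end + ans_delay
                events.append(
                    QuestionEvent(
                        question_id=qid,
                        qtype=qtype,
                        topic=topic,
                        test_index=test,
                        repetition_index=rep,
                        t_question_start=t,
                        t_question_end=t_end,
                        t_answer=t_ans,
                        answer="no" if qtype == "relevant" else "yes",
                    )
                )
                t = t_ans + _POST_WINDOW_GUARD_S + rng.uniform(0.5, 1.5)
        t += _INTERTEST_GAP_S
    return events, t + _TAIL_S


def _simulate_signals(
    config: SimConfig,
    events: Sequence[QuestionEvent],
    duration_s: float,
    deceptive_topics: set[str],
    dropout_tests: dict[str, set[int]],
    rng: np.random.Generator,
) -> list[SignalChannel]:
    rate = config.sampling_rate_hz
    n = int(round(duration_s * rate))
    tgrid = np.arange(n) / rate
    kernel = response_kernel(rate)
    klen = len(kernel)

    r_shared = np.exp(config.subject_sigma * rng.standard_normal())
    channels: list[SignalChannel] = []
    for name in DEFAULT_CHANNELS:
        spec = CHANNEL_MODEL[name]
        r_ch = r_shared * np.exp(config.channel_sigma * rng.standard_normal())
        drift = spec.drift_amp * np.sin(
            2 * np.pi * tgrid / 600.0 + rng.uniform(0, 2 * np.pi)
        )
        periodic = spec.periodic_amp * np.sin(
            2 * np.pi * spec.periodic_freq_hz * tgrid + rng.uniform(0, 2 * np.pi)
        )
        white = rng.standard_normal(n)
        a = config.ar_coeff
        stationary_sd = spec.noise_sd * config.noise_scale
        noise = lfilter([1.0], [1.0, -a], white) * (stationary_sd * np.sqrt(1 - a * a))

        resp = np.zeros(n)
        for ev in events:
            mult = 1.0
            if (
                ev.qtype == "relevant"
                and ev.topic in deceptive_topics
                and ev.test_index not in dropout_tests.get(ev.topic, set())
            ):
                mult = 1.0 + config.effect_size
            amp = (
                spec.kernel_gain
                * r_ch
                * np.exp(config.event_sigma * rng.standard_normal())
                * mult
            )
            i0 = int(round(ev.t_question_start * rate))
            i1 = min(i0 + klen, n)
            resp[i0:i1] += amp * kernel[: i1 - i0]

        samples = spec.baseline + drift + periodic + noise + resp
        channels.append(SignalChannel(name=name, sampling_rate_hz=rate, samples=samples))
    return channels


def _draw_metadata(config: SimConfig, rng: np.random.Generator) -> dict[str, object]:
    doy = int(rng.integers(0, 365))
    return {
        "date": pd.Timestamp("2021-01-01").date() + pd.Timedelta(days=doy),
        "city": config.city,
        "subject_age": int(rng.integers(22, 61)),
        "subject_sex": str(rng.choice(["M", "F"])),
        "subject_type": str(rng.choice(["candidate", "employee"], p=[0.6, 0.4])),
        "current_position": str(rng.choice(_POSITIONS)),
        "current_department": str(rng.choice(_DEPARTMENTS)),
        "accepted_position": str(rng.choice(_POSITIONS)),
        "accepted_department": str(rng.choice(_DEPARTMENTS)),
        "examiner_id": f"E{int(rng.integers(1, config.n_examiners + 1)):02d}",
    }


def simulate_screening(
    config: SimConfig,
    rng: np.random.Generator,
    screening_id: str = "S00000",
    metadata: dict[str, object] | None = None,
) -> tuple[Screening, TruthRecord]:
    """Simulate one screening; examiner labels equal the ground truth.

    Label corruption is a cohort-level step (:func:`inject_examiner_errors`)
    so that realized error rates can be controlled and audited in one place.
    """
    config.validate()
    meta = _draw_metadata(config, rng)
    if metadata:
        meta.update(metadata)

    deceptive = {t for t in config.topics if rng.random() < config.deception_prevalence}
    dropout_tests: dict[str, set[int]] = {}
    if config.per_test_dropout > 0:
        for topic in deceptive:
            dropout_tests[topic] = {
                i
                for i in range(config.tests_per_screening)
                if rng.random() < config.per_test_dropout
            }

    events, duration = _build_schedule(config, rng)
    channels = _simulate_signals(config, events, duration, deceptive, dropout_tests, rng)

    truth = TruthRecord(
        screening_id=screening_id,
        topics={
            t: TopicTruth(
                true_deceptive=(t in deceptive),
                examiner_label="DI" if t in deceptive else "NDI",
            )
            for t in config.topics
        },
    )
    screening = Screening(
        screening_id=screening_id,
        channels=channels,
        events=events,
        conclusions={t: tt.examiner_label for t, tt in truth.topics.items()},
        **meta,  # type: ignore[arg-type]
    )
    return screening, truth


def inject_examiner_errors(
    truths: Sequence[TruthRecord],
    rate: float,
    rng: np.random.Generator,
    mode: str = "symmetric",
) -> list[TruthRecord]:
    """Flip examiner labels independently at ``rate``; truth stays untouched.

    ``symmetric`` flips any conclusion; ``ndi_only`` flips only correct DI
    labels to NDI — the error class a second-opinion tool is built to catch
    (erroneous DI labels are too scarce to validate).
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("error rate must be in [0, 1]")
    if mode not in ("symmetric", "ndi_only"):
        raise ValueError(f"unknown error mode {mode!r}")
    out: list[TruthRecord] = []
    for rec in truths:
        new = TruthRecord(screening_id=rec.screening_id, topics={})
        for topic, tt in rec.topics.items():
            correct = "DI" if tt.true_deceptive else "NDI"
            label = correct
            if mode == "symmetric":
                if rng.random() < rate:
                    label = "NDI" if correct == "DI" else "DI"
            else:
                draw = rng.random()  # one draw per conclusion keeps streams aligned
                if correct == "DI" and draw < rate:
                    label = "NDI"
            new.topics[topic] = TopicTruth(
                true_deceptive=tt.true_deceptive,
                examiner_label=label,
                injected_error=(label != correct),
            )
        out.append(new)
    return out


def apply_examiner_labels(
    screenings: Sequence[Screening], truths: Sequence[TruthRecord]
) -> None:
    """Overwrite each screening's conclusions with the truth records' labels."""
    by_id = {t.screening_id: t for t in truths}
    for s in screenings:
        rec = by_id[s.screening_id]
        s.conclusions = {t: tt.examiner_label for t, tt in rec.topics.items()}


def _weather_row(date, rng: np.random.Generator) -> dict[str, object]:
    doy = pd.Timestamp(date).dayofyear
    temp = 8.0 + 16.0 * np.sin(2 * np.pi * (doy - 105) / 365.0) + rng.normal(0, 3.0)
    humidity = float(np.clip(65.0 + rng.normal(0, 15.0), 5.0, 100.0))
    cond_p = [0.3, 0.3, 0.2, 0.15, 0.05] if temp > 2 else [0.25, 0.25, 0.2, 0.05, 0.25]
    return {
        "Temperature": round(float(temp), 1),
        "Pressure": round(float(rng.normal(1013.0, 8.0)), 1),
        "Humidity": round(humidity, 1),
        "Wind": round(float(rng.uniform(0.0, 360.0)), 0),
        "Wind speed": round(float(abs(rng.normal(4.0, 2.0))), 1),
        "Dew Point": round(float(temp - (100.0 - humidity) / 5.0), 1),
        "Condition": str(rng.choice(_CONDITIONS, p=cond_p)),
    }


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[Screening], list[TruthRecord], pd.DataFrame]:
    """Simulate a full cohort: screenings, truth records, alternative data.

    Deterministic byte-for-byte for a given config (the seed lives in the
    config).  Weather is shared by screenings on the same date (one city).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_screenings + 2)
    screenings: list[Screening] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_screenings):
        rng = np.random.default_rng(children[i])
        s, t = simulate_screening(config, rng, screening_id=f"S{i:05d}")
        screenings.append(s)
        truths.append(t)

    err_rng = np.random.default_rng(children[config.n_screenings])
    truths = inject_examiner_errors(
        truths, config.examiner_error_rate, err_rng, config.error_mode
    )
    apply_examiner_labels(screenings, truths)

    alt_rng = np.random.default_rng(children[config.n_screenings + 1])
    dates = sorted({s.date for s in screenings})
    weather = {d: _weather_row(d, alt_rng) for d in dates}
    alt_rows = []
    for s in screenings:
        row: dict[str, object] = {
            "screening_id": s.screening_id,
            "examiner_id": s.examiner_id,
            "geomagnetic_index": int(
                alt_rng.choice(10, p=[0.12, 0.2, 0.22, 0.16, 0.1, 0.08, 0.05, 0.04, 0.02, 0.01])
            ),
            "Time": round(float(alt_rng.uniform(9.0, 18.0)), 2),
        }
        row.update(weather[s.date])
        alt_rows.append(row)
    alt = pd.DataFrame(alt_rows)
    return screenings, truths, alt


def permute_event_times(
    screening: Screening,
    rng: np.random.Generator,
    post_answer_s: float = 5.0,
) -> Screening:
    """Return a copy whose event windows are placed uniformly at random.

    Each event keeps its internal geometry (question duration, answer
    delay) but its window ``[t_start, t_answer + post_answer_s)`` is moved
    to a uniform random position inside the recording — detaching every
    analysis window from the stimulus it belonged to.  Used for permutation
    null checks of the downstream pipeline.
    """
    out = copy.deepcopy(screening)
    dur = out.duration_s
    for ev in out.events:
        span = (ev.t_answer + post_answer_s) - ev.t_question_start
        if span >= dur:
            continue
        new_start = rng.uniform(0.0, dur - span)
        delta = new_start - ev.t_question_start
        ev.t_question_start += delta
        ev.t_question_end += delta
        ev.t_answer += delta
    return out


def write_cohort(
    screenings: Sequence[Screening],
    truths: Sequence[TruthRecord],
    alt: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write a cohort to disk: one ``.ncca`` file per screening + CSV tables."""
    out_dir = Path(out_dir)
    (out_dir / "screenings").mkdir(parents=True, exist_ok=True)
    for s in screenings:
        write_screening(s, out_dir / "screenings" / f"{s.screening_id}.ncca")
    truth_table(truths).to_csv(out_dir / "truth.csv", index=False)
    alt.to_csv(out_dir / "alt_data.csv", index=False)
    return out_dir
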