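"""Reading, writing and validating polygraph screening recordings.

A polygraph screening recording (PSR) couples ten physiological channels
sampled at a common rate (31 Hz on the target device) with a table of
question events.  Every event carries three timestamps — question start,
question end, and the moment of the examinee's answer — plus a question
type, an optional screening topic, and test/repetition indices.  Per-topic
examiner conclusions (DI = deception indicated, NDI = no deception
indicated) and examinee/examiner metadata complete the record.

Files use a self-contained NCCA-ASCII-style text dialect (UTF-8, ``\\n``
line endings)::

    POLYVERIFY NCCA-ASCII 1.0
    [header]
    screening_id: S00001
    date: 2021-03-05
    ...                       # fixed key order, one ``key: value`` per line
    [conclusions]
    drug_abuse: NDI
    [channel]
    name: EDA
    sampling_rate_hz: 31
    samples: 1.25 1.3 ...     # whitespace-separated, shortest round-trip repr
    [events]
    # question_id qtype topic test repetition t_start t_end t_answer answer
    DA1 relevant drug_abuse 0 0 20.0 22.5 24.1 no
    [end]

Topics absent on an event (comparison/neutral questions) are written as
``-``.  Timestamps are seconds from recording start; analysis windows are
half-open ``[start, end)``.  Writing is byte-deterministic for a given
screening, and ``write → read`` is the identity on the domain model.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

FORMAT_MAGIC = "POLYVERIFY NCCA-ASCII 1.0"

#: Canonical channel set: the seven channels observed in first-level feature
#: names plus three completions.  Configuration-driven — ``validate`` only
#: pins the count (10) unless an explicit set is passed.
DEFAULT_CHANNELS = (
    "THORACIC_RESP",
    "ABDOMINAL_RESP",
    "EDA",
    "TONIC_EDA",
    "PLE",
    "ABS_BLOOD_VOLUME",
    "HEART_RATE",
    "CARDIO",
    "TREMOR",
    "OPTIONAL",
)

N_CHANNELS = len(DEFAULT_CHANNELS)

QUESTION_TYPES = ("relevant", "comparison", "neutral", "other")
ANSWERS = ("yes", "no", "none")
CONCLUSION_VALUES = ("DI", "NDI")

_HEADER_FIELDS = (
    "screening_id",
    "date",
    "city",
    "subject_age",
    "subject_sex",
    "subject_type",
    "current_position",
    "current_department",
    "accepted_position",
    "accepted_department",
    "examiner_id",
)


class NccaError(Exception):
    """Base error for the screening-recording dialect."""


class NccaParseError(NccaError):
    """Malformed file; carries the 1-based line number of the offence."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class NccaValidationError(NccaError):
    """A structurally parseable screening that violates domain invariants."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        super().__init__(
            "screening violates %d invariant(s): %s"
            % (len(self.violations), "; ".join(str(v) for v in self.violations))
        )


@dataclass
class SignalChannel:
    """One physiological channel: a named, uniformly sampled series."""

    name: str
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz


@dataclass
class QuestionEvent:
    """One repetition of one question, with its three timestamps."""

    question_id: str
    qtype: str
    topic: str | None
    test_index: int
    repetition_index: int
    t_question_start: float
    t_question_end: float
    t_answer: float
    answer: str = "no"


@dataclass
class Screening:
    """A full screening recording: channels, events, conclusions, metadata."""

    screening_id: str
    date: _dt.date
    city: str
    subject_age: int
    subject_sex: str
    subject_type: str
    current_position: str
    current_department: str
    accepted_position: str
    accepted_department: str
    examiner_id: str
    channels: list[SignalChannel] = field(default_factory=list)
    events: list[QuestionEvent] = field(default_factory=list)
    conclusions: dict[str, str] = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        if not self.channels:
            return 0.0
        return min(ch.duration_s for ch in self.channels)

    @property
    def topics(self) -> list[str]:
        return sorted(self.conclusions)

    def metadata(self) -> dict[str, object]:
        """Header fields as a plain dict (order matches the file dialect)."""
        return {k: getattr(self, k) for k in _HEADER_FIELDS}

    def relevant_events(
        self, test_index: int | None = None, topic: str | None = None
    ) -> list[QuestionEvent]:
        out = []
        for ev in self.events:
            if ev.qtype != "relevant":
                continue
            if test_index is not None and ev.test_index != test_index:
                continue
            if topic is not None and ev.topic != topic:
                continue
            out.append(ev)
        return out

    def channel(self, name: str) -> SignalChannel:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"no channel named {name!r}")


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the field concerned and the rule it breaks."""

    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.field}: {self.rule} ({self.message})"


def validate(
    screening: Screening, expected_channels: Sequence[str] | None = None
) -> list[Violation]:
    """Check every domain invariant; return one descriptor per violation.

    Total function: never raises on bad content.  ``expected_channels``
    pins an exact channel-name set; by default only the count (10) and
    per-channel rules are enforced.
    """
    v: list[Violation] = []
    s = screening

    expected_n = len(expected_channels) if expected_channels is not None else N_CHANNELS
    if len(s.channels) != expected_n:
        v.append(
            Violation(
                "channels",
                "channel_count",
                f"expected {expected_n} channels, found {len(s.channels)}",
            )
        )
    names = [ch.name for ch in s.channels]
    if len(set(names)) != len(names):
        v.append(Violation("channels", "unique_names", f"duplicate names in {names}"))
    if expected_channels is not None and set(names) != set(expected_channels):
        v.append(
            Violation(
                "channels",
                "canonical_names",
                f"channel set {sorted(names)} != expected {sorted(expected_channels)}",
            )
        )
    lengths = []
    for ch in s.channels:
        if not (ch.sampling_rate_hz > 0):
            v.append(
                Violation(
                    f"channels[{ch.name}].sampling_rate_hz",
                    "positive_rate",
                    f"rate {ch.sampling_rate_hz}",
                )
            )
        if len(ch.samples) == 0:
            v.append(Violation(f"channels[{ch.name}].samples", "nonempty", "no samples"))
        elif not np.isfinite(ch.samples).all():
            bad = int(np.count_nonzero(~np.isfinite(ch.samples)))
            v.append(
                Violation(
                    f"channels[{ch.name}].samples",
                    "finite_samples",
                    f"{bad} non-finite sample(s)",
                )
            )
        lengths.append(len(ch.samples))
    if lengths and max(lengths) - min(lengths) > 1:
        v.append(
            Violation(
                "channels",
                "common_duration",
                f"sample counts differ by more than one: {sorted(set(lengths))}",
            )
        )

    dur = s.duration_s
    for i, ev in enumerate(s.events):
        tag = f"events[{i}]({ev.question_id})"
        if ev.qtype not in QUESTION_TYPES:
            v.append(Violation(f"{tag}.qtype", "known_qtype", repr(ev.qtype)))
        if ev.answer not in ANSWERS:
            v.append(Violation(f"{tag}.answer", "known_answer", repr(ev.answer)))
        if ev.test_index < 0 or ev.repetition_index < 0:
            v.append(
                Violation(
                    f"{tag}.indices",
                    "nonnegative_indices",
                    f"test={ev.test_index} repetition={ev.repetition_index}",
                )
            )
        if not (
            math.isfinite(ev.t_question_start)
            and math.isfinite(ev.t_question_end)
            and math.isfinite(ev.t_answer)
        ):
            v.append(Violation(f"{tag}.timestamps", "finite_timestamps", "non-finite"))
            continue
        if not (0.0 <= ev.t_question_start <= ev.t_question_end <= ev.t_answer):
            v.append(
                Violation(
                    f"{tag}.timestamps",
                    "ordered_timestamps",
                    f"start={ev.t_question_start} end={ev.t_question_end} "
                    f"answer={ev.t_answer}",
                )
            )
        if s.channels and ev.t_answer > dur:
            v.append(
                Violation(
                    f"{tag}.t_answer",
                    "within_recording",
                    f"answer at {ev.t_answer:.3f}s, recording lasts {dur:.3f}s",
                )
            )
        if ev.qtype == "relevant" and not ev.topic:
            v.append(Violation(f"{tag}.topic", "relevant_has_topic", "missing topic"))

    relevant_topics = {ev.topic for ev in s.events if ev.qtype == "relevant" and ev.topic}
    for topic, concl in s.conclusions.items():
        if concl not in CONCLUSION_VALUES:
            v.append(
                Violation(f"conclusions[{topic}]", "known_conclusion", repr(concl))
            )
        if topic not in relevant_topics:
            v.append(
                Violation(
                    f"conclusions[{topic}]",
                    "topic_has_relevant_events",
                    "no relevant question carries this topic",
                )
            )
    return v


def _fmt_float(x: float) -> str:
    # repr of a Python float is the shortest string that round-trips exactly,
    # which makes the writer byte-deterministic and the round trip lossless.
    return repr(float(x))


def write_screening(screening: Screening, path: str | Path) -> Path:
    """Serialize a screening to the text dialect; refuse invalid input.

    Identical screenings produce byte-identical files.
    """
    violations = validate(screening)
    if violations:
        raise NccaValidationError(violations)
    path = Path(path)
    lines: list[str] = [FORMAT_MAGIC, "[header]"]
    for key in _HEADER_FIELDS:
        value = getattr(screening, key)
        if isinstance(value, _dt.date):
            value = value.isoformat()
        text = str(value)
        if "\n" in text:
            raise NccaError(f"header field {key} contains a newline")
        lines.append(f"{key}: {text}")
    lines.append("[conclusions]")
    for topic in sorted(screening.conclusions):
        lines.append(f"{topic}: {screening.conclusions[topic]}")
    for ch in screening.channels:
        lines.append("[channel]")
        lines.append(f"name: {ch.name}")
        lines.append(f"sampling_rate_hz: {_fmt_float(ch.sampling_rate_hz)}")
        lines.append("samples: " + " ".join(_fmt_float(x) for x in ch.samples))
    lines.append("[events]")
    lines.append("# question_id qtype topic test repetition t_start t_end t_answer answer")
    for ev in screening.events:
        if any(c.isspace() for c in ev.question_id):
            raise NccaError(f"question_id {ev.question_id!r} contains whitespace")
        lines.append(
            " ".join(
                (
                    ev.question_id,
                    ev.qtype,
                    ev.topic if ev.topic else "-",
                    str(ev.test_index),
                    str(ev.repetition_index),
                    _fmt_float(ev.t_question_start),
                    _fmt_float(ev.t_question_end),
                    _fmt_float(ev.t_answer),
                    ev.answer,
                )
            )
        )
    lines.append("[end]")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def _parse_header_value(key: str, raw: str, line_no: int) -> object:
    if key == "date":
        try:
            return _dt.date.fromisoformat(raw)
        except ValueError as exc:
            raise NccaParseError(line_no, f"bad date {raw!r}: {exc}") from None
    if key == "subject_age":
        try:
            return int(raw)
        except ValueError:
            raise NccaParseError(line_no, f"bad subject_age {raw!r}") from None
    return raw


def read_screening(
    path: str | Path, expected_channels: Sequence[str] | None = None
) -> Screening:
    """Parse and validate a screening file.

    Raises :class:`NccaParseError` (with the offending line number) on
    malformed content and :class:`NccaValidationError` when the parsed
    screening breaks a domain invariant (e.g. unordered timestamps).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != FORMAT_MAGIC:
        raise NccaParseError(1, f"missing magic line {FORMAT_MAGIC!r}")

    header: dict[str, object] = {}
    conclusions: dict[str, str] = {}
    channels: list[SignalChannel] = []
    events: list[QuestionEvent] = []
    section: str | None = None
    chan_buf: dict[str, object] = {}

    def flush_channel(line_no: int) -> None:
        if not chan_buf:
            return
        missing = {"name", "sampling_rate_hz", "samples"} - set(chan_buf)
        if missing:
            raise NccaParseError(line_no, f"channel block missing {sorted(missing)}")
        channels.append(
            SignalChannel(
                name=str(chan_buf["name"]),
                sampling_rate_hz=float(chan_buf["sampling_rate_hz"]),  # type: ignore[arg-type]
                samples=chan_buf["samples"],  # type: ignore[arg-type]
            )
        )
        chan_buf.clear()

    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("["):
            if line not in ("[header]", "[conclusions]", "[channel]", "[events]", "[end]"):
                raise NccaParseError(line_no, f"unknown section {line!r}")
            flush_channel(line_no)
            section = line[1:-1]
            continue
        if section in ("header", "conclusions", "channel"):
            if ":" not in line:
                raise NccaParseError(line_no, f"expected 'key: value', got {line!r}")
            key, _, raw = line.partition(":")
            key, raw = key.strip(), raw.strip()
            if section == "header":
                if key not in _HEADER_FIELDS:
                    raise NccaParseError(line_no, f"unknown header field {key!r}")
                header[key] = _parse_header_value(key, raw, line_no)
            elif section == "conclusions":
                conclusions[key] = raw
            else:
                if key == "samples":
                    try:
                        chan_buf["samples"] = np.array(raw.split(), dtype=float)
                    except ValueError:
                        raise NccaParseError(line_no, "non-numeric value in samples") from None
                elif key == "sampling_rate_hz":
                    try:
                        chan_buf[key] = float(raw)
                    except ValueError:
                        raise NccaParseError(line_no, f"bad rate {raw!r}") from None
                else:
                    chan_buf[key] = raw
        elif section == "events":
            parts = line.split()
            if len(parts) != 9:
                raise NccaParseError(
                    line_no, f"event line needs 9 fields, got {len(parts)}"
                )
            qid, qtype, topic, test, rep, t0, t1, t2, answer = parts
            try:
                events.append(
                    QuestionEvent(
                        question_id=qid,
                        qtype=qtype,
                        topic=None if topic == "-" else topic,
                        test_index=int(test),
                        repetition_index=int(rep),
                        t_question_start=float(t0),
                        t_question_end=float(t1),
                        t_answer=float(t2),
                        answer=answer,
                    )
                )
            except ValueError as exc:
                raise NccaParseError(line_no, f"bad event field: {exc}") from None
        elif section == "end":
            raise NccaParseError(line_no, "content after [end]")
        else:
            raise NccaParseError(line_no, f"content outside any section: {line!r}")

    flush_channel(len(lines) + 1)
    missing = set(_HEADER_FIELDS) - set(header)
    if missing:
        raise NccaParseError(len(lines), f"header missing fields {sorted(missing)}")

    screening = Screening(
        channels=channels, events=events, conclusions=conclusions, **header  # type: ignore[arg-type]
    )
    violations = validate(screening, expected_channels)
    if violations:
        raise NccaValidationError(violations)
    return screening


def screenings_equal(a: Screening, b: Screening, tol: float = 1e-9) -> bool:
    """Field-by-field equality with a numeric tolerance on floats."""
    if a.metadata() != b.metadata() or a.conclusions != b.conclusions:
        return False
    if len(a.channels) != len(b.channels) or len(a.events) != len(b.events):
        return False
    for ca, cb in zip(a.channels, b.channels):
        if ca.name != cb.name or abs(ca.sampling_rate_hz - cb.sampling_rate_hz) > tol:
            return False
        if len(ca.samples) != len(cb.samples):
            return False
        if not np.allclose(ca.samples, cb.samples, rtol=0.0, atol=tol):
            return False
    for ea, eb in zip(a.events, b.events):
        da, db = dataclasses.asdict(ea), dataclasses.asdict(eb)
        for k in ("t_question_start", "t_question_end", "t_answer"):
            if abs(da.pop(k) - db.pop(k)) > tol:
                return False
        if da != db:
            return False
    return True
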