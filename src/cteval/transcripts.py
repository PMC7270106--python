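"""Data model, file I/O and normalization for therapy-session transcripts.

A session is represented twice: a *reference* transcript produced by human
scribes (diarized into therapist / patient / unknown utterances, each
change of speaker timestamped) and a *hypothesis* transcript produced by
an ASR system, which may lack diarization and timing.  Evaluation happens
on a :class:`SessionPair`, which carves both token streams into units —
one per reference utterance — so every metric can be reported per
utterance, per speaker and per session.

Two plain-text dialects are supported.  TSV: one utterance per line,
``speaker<TAB>start<TAB>text`` with ``#``-prefixed header lines for the
session id and speaker metadata; start times accept ``MM:SS`` or plain
seconds, or ``-`` when unknown.  JSON: a single object with
``session_id``, ``speakers`` and an ``utterances`` array.
"""

from __future__ import annotations

import json
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Optional, Union

from .alignment import Alignment, align_words
from .errors import PairingModeError, TranscriptParseError, ValidationError

__all__ = [
    "Speaker",
    "NormalizationConfig",
    "DEFAULT_NORMALIZATION",
    "FILLER_WORDS",
    "normalize_tokens",
    "SpeakerInfo",
    "Utterance",
    "SessionTranscript",
    "Unit",
    "SessionPair",
    "parse_transcript",
    "write_transcript",
    "pair_sessions",
]


class Speaker(str, Enum):
    THERAPIST = "therapist"
    PATIENT = "patient"
    UNKNOWN = "unknown"

    @classmethod
    def coerce(cls, value: Union[str, "Speaker"]) -> "Speaker":
        """Map arbitrary speaker labels onto the three-way enum.

        ``t``/``therapist`` and ``p``/``patient`` (any case) are
        recognised; anything else becomes :attr:`UNKNOWN`.
        """
        if isinstance(value, Speaker):
            return value
        v = str(value).strip().lower()
        if v in ("t", "therapist"):
            return cls.THERAPIST
        if v in ("p", "patient"):
            return cls.PATIENT
        return cls.UNKNOWN


#: Filler words scribes transcribe verbatim; retained by default and
#: removable with ``keep_fillers=False`` for sensitivity analyses.
FILLER_WORDS = frozenset(
    ["uh", "um", "er", "ah", "hm", "hmm", "mhm", "mm", "huh", "mm-hm", "mmhm", "uh-huh", "erm"]
)

# a word is a run of word characters optionally joined by internal
# apostrophes or hyphens; leading/trailing punctuation falls away
_WORD_RE = re.compile(r"\w+(?:['\-]\w+)*")
_TRANSLATE = str.maketrans({"’": "'", "‘": "'", "–": "-", "—": "-"})


@dataclass(frozen=True)
class NormalizationConfig:
    """Tokenization rules applied identically to both transcripts.

    Defaults follow WER-literature convention: lowercase, strip
    punctuation except intra-word apostrophes/hyphens, keep fillers,
    collapse whitespace.  Numerals are kept as written.
    """

    lowercase: bool = True
    strip_punctuation: bool = True
    keep_fillers: bool = True
    collapse_whitespace: bool = True


DEFAULT_NORMALIZATION = NormalizationConfig()


def normalize_tokens(text: str, cfg: NormalizationConfig = DEFAULT_NORMALIZATION) -> list[str]:
    """Normalize raw text into a list of word tokens.

    Idempotent: ``normalize_tokens(" ".join(tokens))`` returns ``tokens``
    again.  Empty or punctuation-only input yields an empty list.
    """
    text = text.translate(_TRANSLATE)
    if cfg.lowercase:
        text = text.lower()
    if cfg.strip_punctuation:
        tokens = _WORD_RE.findall(text)
    elif cfg.collapse_whitespace:
        tokens = text.split()
    else:
        tokens = [t for t in text.split(" ") if t]
    if not cfg.keep_fillers:
        tokens = [t for t in tokens if t not in FILLER_WORDS]
    return tokens


@dataclass(frozen=True)
class SpeakerInfo:
    gender: Optional[str] = None
    age: Optional[float] = None


@dataclass(frozen=True)
class Utterance:
    """A contiguous single-speaker stretch of speech as transcribed."""

    speaker: Speaker
    raw_text: str
    start_time: Optional[float] = None  # seconds from session start
    tokens: tuple[str, ...] = ()

    @classmethod
    def create(
        cls,
        speaker: Union[str, Speaker],
        raw_text: str,
        start_time: Optional[float] = None,
        cfg: NormalizationConfig = DEFAULT_NORMALIZATION,
    ) -> "Utterance":
        return cls(
            speaker=Speaker.coerce(speaker),
            raw_text=raw_text,
            start_time=start_time,
            tokens=tuple(normalize_tokens(raw_text, cfg)),
        )


@dataclass(frozen=True)
class SessionTranscript:
    session_id: str
    source: str  # "reference" | "hypothesis"
    utterances: tuple[Utterance, ...] = ()
    speaker_metadata: dict[str, SpeakerInfo] = field(default_factory=dict)
    normalization: NormalizationConfig = DEFAULT_NORMALIZATION

    def __post_init__(self) -> None:
        if self.source not in ("reference", "hypothesis"):
            raise ValidationError(f"source must be reference|hypothesis, got {self.source!r}")
        last = None
        for k, u in enumerate(self.utterances):
            if u.start_time is not None:
                if u.start_time < 0:
                    raise ValidationError(f"utterance {k}: negative start time {u.start_time}")
                if last is not None and u.start_time < last:
                    raise ValidationError(
                        f"utterance {k}: start time {u.start_time} decreases below {last}"
                    )
                last = u.start_time

    def tokens(self) -> list[str]:
        """Flat token stream over all utterances, in order."""
        out: list[str] = []
        for u in self.utterances:
            out.extend(u.tokens)
        return out

    @property
    def word_count(self) -> int:
        return sum(len(u.tokens) for u in self.utterances)

    def speaker_word_count(self, speaker: Union[str, Speaker]) -> int:
        sp = Speaker.coerce(speaker)
        return sum(len(u.tokens) for u in self.utterances if u.speaker is sp)


def _parse_time(text: str, line_no: int) -> Optional[float]:
    text = text.strip()
    if text in ("", "-"):
        return None
    if ":" in text:
        parts = text.split(":")
        if len(parts) != 2:
            raise TranscriptParseError(f"line {line_no}: bad MM:SS time {text!r}")
        try:
            return int(parts[0]) * 60.0 + float(parts[1])
        except ValueError as exc:
            raise TranscriptParseError(f"line {line_no}: bad MM:SS time {text!r}") from exc
    try:
        return float(text)
    except ValueError as exc:
        raise TranscriptParseError(f"line {line_no}: bad time {text!r}") from exc


def _coerce_stream(source: Union[str, Path, IO[str]], mode: str) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def _infer_dialect(source: Union[str, Path, IO[str]]) -> str:
    if isinstance(source, (str, Path)) and str(source).endswith(".json"):
        return "json"
    return "tsv"


def parse_transcript(
    source: Union[str, Path, IO[str]],
    dialect: Optional[str] = None,
    *,
    default_source: str = "reference",
    cfg: NormalizationConfig = DEFAULT_NORMALIZATION,
    session_id: Optional[str] = None,
) -> SessionTranscript:
    """Read a transcript from a path or text stream.

    ``dialect`` is ``"tsv"`` or ``"json"``; inferred from a ``.json``
    suffix when omitted.  Speaker labels outside therapist/patient map to
    ``unknown``.  Raises :class:`TranscriptParseError` (naming the line)
    on malformed records and :class:`ValidationError` on non-monotone
    timestamps.
    """
    dialect = dialect or _infer_dialect(source)
    stream, close = _coerce_stream(source, "r")
    try:
        if dialect == "json":
            return _parse_json(stream, default_source, cfg, session_id)
        if dialect == "tsv":
            return _parse_tsv(stream, default_source, cfg, session_id)
        raise ValidationError(f"unknown dialect {dialect!r}")
    finally:
        if close:
            stream.close()


def _parse_tsv(stream, default_source, cfg, session_id):
    sid = session_id or "session"
    source = default_source
    meta: dict[str, SpeakerInfo] = {}
    utterances: list[Utterance] = []
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if not fields:
                continue
            key = fields[0].rstrip(":")
            if key == "session_id" and len(fields) > 1:
                sid = fields[1]
            elif key == "source" and len(fields) > 1:
                source = fields[1]
            elif key == "speaker" and len(fields) > 1:
                name = fields[1]
                kv = dict(f.split("=", 1) for f in fields[2:] if "=" in f)
                age = float(kv["age"]) if kv.get("age") not in (None, "", "-") else None
                gender = kv.get("gender") or None
                meta[name] = SpeakerInfo(gender=gender, age=age)
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise TranscriptParseError(
                f"line {line_no}: expected speaker<TAB>start<TAB>text, got {len(parts)} fields"
            )
        speaker, start, text = parts
        utterances.append(Utterance.create(speaker, text, _parse_time(start, line_no), cfg))
    return SessionTranscript(
        session_id=sid,
        source=source,
        utterances=tuple(utterances),
        speaker_metadata=meta,
        normalization=cfg,
    )


def _parse_json(stream, default_source, cfg, session_id):
    try:
        doc = json.load(stream)
    except json.JSONDecodeError as exc:
        raise TranscriptParseError(f"line {exc.lineno}: invalid JSON ({exc.msg})") from exc
    meta = {
        name: SpeakerInfo(gender=info.get("gender"), age=info.get("age"))
        for name, info in (doc.get("speakers") or {}).items()
    }
    utterances = []
    for k, rec in enumerate(doc.get("utterances", [])):
        if "text" not in rec or "speaker" not in rec:
            raise TranscriptParseError(f"utterance {k}: missing 'speaker' or 'text'")
        utterances.append(Utterance.create(rec["speaker"], rec["text"], rec.get("start"), cfg))
    return SessionTranscript(
        session_id=session_id or doc.get("session_id", "session"),
        source=doc.get("source", default_source),
        utterances=tuple(utterances),
        speaker_metadata=meta,
        normalization=cfg,
    )


def write_transcript(
    transcript: SessionTranscript,
    target: Union[str, Path, IO[str]],
    dialect: Optional[str] = None,
) -> None:
    """Write a transcript in the TSV or JSON dialect (UTF-8).

    ``parse_transcript(write_transcript(t))`` round-trips all fields.
    TSV cannot carry tabs or newlines inside utterance text and raises
    :class:`ValidationError` if asked to.
    """
    dialect = dialect or _infer_dialect(target)
    stream, close = _coerce_stream(target, "w")
    try:
        if dialect == "json":
            doc = {
                "session_id": transcript.session_id,
                "source": transcript.source,
                "speakers": {
                    name: {"gender": info.gender, "age": info.age}
                    for name, info in transcript.speaker_metadata.items()
                },
                "utterances": [
                    {"speaker": u.speaker.value, "start": u.start_time, "text": u.raw_text}
                    for u in transcript.utterances
                ],
            }
            json.dump(doc, stream, ensure_ascii=False, indent=1)
            stream.write("\n")
        elif dialect == "tsv":
            stream.write(f"# session_id {transcript.session_id}\n")
            stream.write(f"# source {transcript.source}\n")
            for name, info in transcript.speaker_metadata.items():
                parts = [f"# speaker {name}"]
                if info.gender:
                    parts.append(f"gender={info.gender}")
                if info.age is not None:
                    parts.append(f"age={info.age:g}")
                stream.write(" ".join(parts) + "\n")
            for u in transcript.utterances:
                if "\t" in u.raw_text or "\n" in u.raw_text:
                    raise ValidationError("TSV dialect cannot encode tabs/newlines in text")
                start = "-" if u.start_time is None else f"{u.start_time:g}"
                stream.write(f"{u.speaker.value}\t{start}\t{u.raw_text}\n")
        else:
            raise ValidationError(f"unknown dialect {dialect!r}")
    finally:
        if close:
            stream.close()


@dataclass(frozen=True)
class Unit:
    """One evaluable unit: a reference utterance with its hypothesis span."""

    ref_indices: tuple[int, ...]
    hyp_span: tuple[int, int]  # half-open into the flat hypothesis stream
    ref_tokens: tuple[str, ...]
    hyp_tokens: tuple[str, ...]
    speaker: Speaker


@dataclass
class SessionPair:
    """A reference/hypothesis transcript pair carved into units.

    Every reference utterance appears in exactly one unit; hypothesis
    token spans are disjoint and in order.
    """

    reference: SessionTranscript
    hypothesis: SessionTranscript
    units: tuple[Unit, ...]
    mode: str
    _unit_alignments: Optional[tuple[Alignment, ...]] = field(
        default=None, repr=False, compare=False
    )

    @property
    def session_id(self) -> str:
        return self.reference.session_id

    def unit_alignments(self) -> tuple[Alignment, ...]:
        """Per-unit word alignments, computed once and cached."""
        if self._unit_alignments is None:
            self._unit_alignments = tuple(
                align_words(u.ref_tokens, u.hyp_tokens) for u in self.units
            )
        return self._unit_alignments


def _utterance_token_offsets(t: SessionTranscript) -> list[int]:
    offsets = [0]
    for u in t.utterances:
        offsets.append(offsets[-1] + len(u.tokens))
    return offsets


def pair_sessions(
    ref: SessionTranscript, hyp: SessionTranscript, mode: str = "global_align"
) -> SessionPair:
    """Pair a reference with a hypothesis transcript into units.

    ``global_align`` (default) aligns the two full token streams and
    projects reference utterance boundaries through the alignment, so it
    works for undiarized, untimed ASR output.  ``timestamp`` reproduces
    timing-based pairing: each hypothesis token is assigned to the
    reference utterance whose time window contains it (hypothesis word
    times are interpolated within utterances); it requires start times on
    both sides.
    """
    if ref.session_id != hyp.session_id:
        raise ValidationError(
            f"session ids differ: {ref.session_id!r} vs {hyp.session_id!r}"
        )
    ref_tokens = ref.tokens()
    hyp_tokens = hyp.tokens()
    n_utt = len(ref.utterances)
    if n_utt == 0:
        return SessionPair(ref, hyp, (), mode)
    if mode == "global_align":
        hyp_bounds = _project_boundaries(ref, hyp, ref_tokens, hyp_tokens)
    elif mode == "timestamp":
        hyp_bounds = _timestamp_boundaries(ref, hyp)
    else:
        raise ValidationError(f"unknown pairing mode {mode!r}")
    ref_offsets = _utterance_token_offsets(ref)
    units = []
    for i in range(n_utt):
        lo, hi = hyp_bounds[i], hyp_bounds[i + 1]
        units.append(
            Unit(
                ref_indices=(i,),
                hyp_span=(lo, hi),
                ref_tokens=tuple(ref_tokens[ref_offsets[i] : ref_offsets[i + 1]]),
                hyp_tokens=tuple(hyp_tokens[lo:hi]),
                speaker=ref.utterances[i].speaker,
            )
        )
    return SessionPair(ref, hyp, tuple(units), mode)


def _project_boundaries(ref, hyp, ref_tokens, hyp_tokens) -> list[int]:
    """Hypothesis-token boundaries of each reference utterance via a
    global word alignment.

    Each matched/substituted hypothesis token inherits the utterance of
    its reference partner; inserted tokens join the utterance of the next
    anchored token (trailing insertions join the last utterance).
    """
    ref_offsets = _utterance_token_offsets(ref)
    # utterance index for each flat reference token
    utt_of_ref = [0] * len(ref_tokens)
    for i in range(len(ref.utterances)):
        for k in range(ref_offsets[i], ref_offsets[i + 1]):
            utt_of_ref[k] = i
    alignment = align_words(ref_tokens, hyp_tokens)
    unit_of_hyp = [len(ref.utterances) - 1] * len(hyp_tokens)
    pending: list[int] = []
    for op in alignment.ops:
        if op.kind in ("match", "substitution"):
            u = utt_of_ref[op.ref_index]
            unit_of_hyp[op.hyp_index] = u
            for j in pending:
                unit_of_hyp[j] = u
            pending.clear()
        elif op.kind == "insertion":
            pending.append(op.hyp_index)
    # pending trailing insertions keep the default (last utterance);
    # starts[i] = first flat hypothesis index belonging to utterance i
    starts = []
    j = 0
    for i in range(len(ref.utterances)):
        while j < len(hyp_tokens) and unit_of_hyp[j] < i:
            j += 1
        starts.append(j)
    starts.append(len(hyp_tokens))
    return starts


def _timestamp_boundaries(ref, hyp) -> list[int]:
    if any(u.start_time is None for u in ref.utterances):
        raise PairingModeError("timestamp mode requires start times on all reference utterances")
    if any(u.start_time is None for u in hyp.utterances):
        raise PairingModeError("timestamp mode requires start times on all hypothesis utterances")
    # interpolate a time for every hypothesis token within its utterance
    token_times: list[float] = []
    utts = hyp.utterances
    for k, u in enumerate(utts):
        n = len(u.tokens)
        if n == 0:
            continue
        start = float(u.start_time)
        if k + 1 < len(utts):
            end = float(utts[k + 1].start_time)
        else:
            end = start + n / 2.5  # ~150 words per minute for the tail
        dur = max(end - start, 0.0)
        for i in range(n):
            token_times.append(start + dur * i / n)
    # reference windows are [start_i, start_{i+1}); each token joins the
    # last window whose start <= its time, clamping early tokens to 0
    ref_starts = [float(u.start_time) for u in ref.utterances]
    unit_of_tok = [max(0, bisect_right(ref_starts, t) - 1) for t in token_times]
    out = []
    j = 0
    for i in range(len(ref_starts)):
        while j < len(unit_of_tok) and unit_of_tok[j] < i:
            j += 1
        out.append(j)
    out.append(len(token_times))
    return out
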