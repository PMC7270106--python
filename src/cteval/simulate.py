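"""Synthetic paired transcripts with a known, controllable error channel.

Real psychotherapy recordings and their transcripts are private, so every
metric in this package is exercised on synthetic two-speaker sessions
whose shape matches published session profiles: the therapist speaks
about 2909 ± 1128 words per session and the patient 3665 ± 1550
(truncated-normal draws), in alternating utterances of ~15 words.
Clinical keywords from the PHQ-9 lexicon are injected at a configurable
per-position rate (default 0.0016, matching roughly one thousand keyword
occurrences per hundred sessions).

The error channel is an independent per-token process: each reference
token is substituted with probability ``sub_rate`` (drawn from a
homophone confusion table when one is available, otherwise a random
different vocabulary word) or deleted with probability ``del_rate``;
after every token a random word is inserted with probability
``ins_rate``.  Tokens inside keyword spans use substitution/deletion
rates scaled by ``keyword_error_multiplier`` (total capped at 1), so
keyword-level sensitivity can be dialled independently of the base WER.
The exact injected op log is returned as ground truth, which upper-bounds
the measured WER (an optimal aligner can only find a cheaper script) and
pins down the true outcome of every keyword occurrence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .lexicon import KeywordLexicon, build_phq9_lexicon, find_keyword_spans
from .transcripts import (
    SessionPair,
    SessionTranscript,
    Speaker,
    SpeakerInfo,
    Utterance,
    pair_sessions,
    write_transcript,
)

__all__ = [
    "SessionProfile",
    "CorruptionConfig",
    "GroundTruth",
    "synthetic_vocabulary",
    "default_confusion_table",
    "generate_reference_session",
    "corrupt_session",
    "expected_error_rate",
    "build_paired_cohort",
    "write_cohort",
]

_WORDS_PER_SECOND = 2.5  # ~150 words/min speaking rate for timestamps


def synthetic_vocabulary(size: int = 5000) -> list[str]:
    """Distinct integer-spelled words ("w0" … ), guaranteed disjoint from
    the PHQ-9 lexicon so random substitutions never create keywords."""
    return [f"w{i}" for i in range(size)]


def default_confusion_table() -> dict[str, list[str]]:
    """Homophone / near-phone confusion sets shipped as data."""
    text = resources.files("cteval.data").joinpath("homophones.yaml").read_text("utf-8")
    return {str(k): [str(v) for v in vs] for k, vs in yaml.safe_load(text)["confusions"].items()}


@dataclass(frozen=True)
class SessionProfile:
    """Shape of a synthetic session; defaults follow the published
    per-session word-count profiles (mean/SD per speaker)."""

    therapist_words: tuple[float, float] = (2909.0, 1128.0)
    patient_words: tuple[float, float] = (3665.0, 1550.0)
    utterance_length: float = 15.0  # mean tokens per speaker turn
    keyword_rate: float = 0.0016  # prob. a token position starts a keyword
    vocabulary: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.keyword_rate <= 1.0):
            raise ValidationError(f"keyword_rate must be in [0,1], got {self.keyword_rate}")
        for name, (mean, sd) in (
            ("therapist_words", self.therapist_words),
            ("patient_words", self.patient_words),
        ):
            if mean <= 0 or sd < 0:
                raise ValidationError(f"{name}: mean must be positive, sd non-negative")
            if mean + 6 * sd < 1:
                raise ValidationError(f"{name}: truncation at 1 word leaves no mass")
        if self.utterance_length < 1:
            raise ValidationError("utterance_length must be >= 1")


@dataclass(frozen=True)
class CorruptionConfig:
    """Per-token error channel parameters; ``sub_rate + del_rate <= 1``."""

    sub_rate: float = 0.1
    del_rate: float = 0.05
    ins_rate: float = 0.05
    confusion_table: Optional[dict[str, list[str]]] = None
    keyword_error_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "del_rate", "ins_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.sub_rate + self.del_rate > 1.0:
            raise ValidationError("sub_rate + del_rate must not exceed 1")
        if self.keyword_error_multiplier < 0:
            raise ValidationError("keyword_error_multiplier must be >= 0")


@dataclass(frozen=True)
class InjectedOp:
    kind: str  # "substitution" | "deletion" | "insertion"
    ref_index: Optional[int]  # flat reference token index (insertion: gap after it)
    original: Optional[str]
    replacement: Optional[str]


@dataclass(frozen=True)
class KeywordOutcome:
    start: int
    end: int
    keyword: tuple[str, ...]
    category_id: int
    transcribed: bool  # True when no sub/del touched the span


@dataclass(frozen=True)
class GroundTruth:
    """The injected error script for one corrupted session."""

    injected_ops: tuple[InjectedOp, ...]
    injected_S: int
    injected_D: int
    injected_I: int
    n_ref_tokens: int
    keyword_outcomes: tuple[KeywordOutcome, ...]

    @property
    def injected_error_rate(self) -> float:
        if self.n_ref_tokens == 0:
            return 0.0
        return (self.injected_S + self.injected_D + self.injected_I) / self.n_ref_tokens


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def _truncated_normal_count(rng, mean: float, sd: float) -> int:
    """Word total >= 1 by rejection; the profile validator guarantees the
    truncated region has usable mass."""
    for _ in range(10000):
        v = rng.normal(mean, sd)
        if v >= 1.0:
            return int(round(v))
    raise ValidationError(f"could not draw a positive word count from N({mean}, {sd})")


def generate_reference_session(
    profile: SessionProfile,
    lexicon: Optional[KeywordLexicon] = None,
    session_id: Optional[str] = None,
) -> SessionTranscript:
    """Generate one diarized, timestamped reference session.

    Speakers alternate (therapist first); per-speaker word totals are
    truncated-normal draws; utterance lengths are 1 + Poisson(mean−1).
    With probability ``keyword_rate`` a token position starts a keyword
    drawn uniformly from the lexicon (multiword keywords emit all their
    tokens); other positions draw uniformly from the vocabulary.
    Deterministic under the profile seed.
    """
    lexicon = lexicon or build_phq9_lexicon()
    vocab = list(profile.vocabulary) if profile.vocabulary is not None else synthetic_vocabulary()
    if not vocab:
        raise ValidationError("vocabulary must be nonempty")
    keywords = [kw for kw, _ in lexicon.all_keywords()]
    rng = _rng(profile.seed, 0)
    totals = {
        Speaker.THERAPIST: _truncated_normal_count(rng, *profile.therapist_words),
        Speaker.PATIENT: _truncated_normal_count(rng, *profile.patient_words),
    }
    remaining = dict(totals)
    order = [Speaker.THERAPIST, Speaker.PATIENT]
    utterances: list[Utterance] = []
    t = 0.0
    turn = 0
    while any(v > 0 for v in remaining.values()):
        sp = order[turn % 2]
        turn += 1
        if remaining[sp] <= 0:
            continue
        length = min(remaining[sp], 1 + int(rng.poisson(profile.utterance_length - 1.0)))
        tokens: list[str] = []
        while len(tokens) < length:
            if profile.keyword_rate > 0 and rng.random() < profile.keyword_rate:
                tokens.extend(keywords[int(rng.integers(len(keywords)))])
            else:
                tokens.append(vocab[int(rng.integers(len(vocab)))])
        remaining[sp] -= len(tokens)
        utterances.append(
            Utterance(
                speaker=sp,
                raw_text=" ".join(tokens),
                start_time=round(t, 2),
                tokens=tuple(tokens),
            )
        )
        t += len(tokens) / _WORDS_PER_SECOND
    return SessionTranscript(
        session_id=session_id or f"synthetic-{profile.seed}",
        source="reference",
        utterances=tuple(utterances),
        speaker_metadata={
            Speaker.PATIENT.value: SpeakerInfo(gender="female", age=23.0),
            Speaker.THERAPIST.value: SpeakerInfo(),
        },
    )


def _keyword_rates(cfg: CorruptionConfig) -> tuple[float, float]:
    """Substitution/deletion rates for tokens inside keyword spans: base
    rates scaled by the multiplier, jointly capped at total prob. 1."""
    s = cfg.sub_rate * cfg.keyword_error_multiplier
    d = cfg.del_rate * cfg.keyword_error_multiplier
    total = s + d
    if total > 1.0:
        s, d = s / total, d / total
    return s, d


def corrupt_session(
    ref: SessionTranscript,
    cfg: CorruptionConfig,
    lexicon: Optional[KeywordLexicon] = None,
    vocabulary: Optional[Sequence[str]] = None,
) -> tuple[SessionTranscript, GroundTruth]:
    """Push a reference session through the error channel.

    Returns the hypothesis transcript (same utterance structure and
    timestamps, corrupted tokens) and the exact injected op log with the
    true outcome of every keyword occurrence.  Random substitutes and
    insertions draw from ``vocabulary`` (default: the synthetic one).
    """
    lexicon = lexicon or build_phq9_lexicon()
    vocab = list(vocabulary) if vocabulary is not None else synthetic_vocabulary()
    confusion = cfg.confusion_table
    rng = _rng(cfg.seed, 1)
    flat = ref.tokens()
    spans = find_keyword_spans(flat, lexicon)
    in_keyword = np.zeros(len(flat), dtype=bool)
    for s in spans:
        in_keyword[s.start : s.end] = True
    ks, kd = _keyword_rates(cfg)

    ops: list[InjectedOp] = []
    touched = np.zeros(len(flat), dtype=bool)  # sub/del hit this ref token
    out_tokens: list[list[str]] = []
    flat_idx = 0
    for u in ref.utterances:
        hyp_toks: list[str] = []
        for tok in u.tokens:
            srate, drate = (ks, kd) if in_keyword[flat_idx] else (cfg.sub_rate, cfg.del_rate)
            r = rng.random()
            if r < srate:
                repl = _substitute(tok, confusion, vocab, rng)
                hyp_toks.append(repl)
                ops.append(InjectedOp("substitution", flat_idx, tok, repl))
                touched[flat_idx] = True
            elif r < srate + drate:
                ops.append(InjectedOp("deletion", flat_idx, tok, None))
                touched[flat_idx] = True
            else:
                hyp_toks.append(tok)
            if cfg.ins_rate > 0 and rng.random() < cfg.ins_rate:
                ins = vocab[int(rng.integers(len(vocab)))]
                hyp_toks.append(ins)
                ops.append(InjectedOp("insertion", flat_idx, None, ins))
            flat_idx += 1
        out_tokens.append(hyp_toks)

    utterances = tuple(
        Utterance(
            speaker=u.speaker,
            raw_text=" ".join(toks),
            start_time=u.start_time,
            tokens=tuple(toks),
        )
        for u, toks in zip(ref.utterances, out_tokens)
    )
    hyp = SessionTranscript(
        session_id=ref.session_id,
        source="hypothesis",
        utterances=utterances,
        speaker_metadata=dict(ref.speaker_metadata),
    )
    outcomes = tuple(
        KeywordOutcome(
            start=s.start,
            end=s.end,
            keyword=s.keyword,
            category_id=s.category_id,
            transcribed=not bool(touched[s.start : s.end].any()),
        )
        for s in spans
    )
    truth = GroundTruth(
        injected_ops=tuple(ops),
        injected_S=sum(1 for o in ops if o.kind == "substitution"),
        injected_D=sum(1 for o in ops if o.kind == "deletion"),
        injected_I=sum(1 for o in ops if o.kind == "insertion"),
        n_ref_tokens=len(flat),
        keyword_outcomes=outcomes,
    )
    return hyp, truth


def _substitute(tok: str, confusion, vocab, rng) -> str:
    if confusion and tok in confusion and confusion[tok]:
        cands = confusion[tok]
        return cands[int(rng.integers(len(cands)))]
    for _ in range(100):
        w = vocab[int(rng.integers(len(vocab)))]
        if w != tok:
            return w
    raise ValidationError("vocabulary too small to draw a distinct substitute")


def expected_error_rate(cfg: CorruptionConfig) -> float:
    """Expected injected ops per reference token,
    ``sub_rate + del_rate + ins_rate`` (keyword multiplier ignored, i.e.
    the keyword-free expectation)."""
    return cfg.sub_rate + cfg.del_rate + cfg.ins_rate


def build_paired_cohort(
    n_sessions: int,
    profile: Optional[SessionProfile] = None,
    cfg: Optional[CorruptionConfig] = None,
    lexicon: Optional[KeywordLexicon] = None,
    mode: str = "global_align",
) -> list[tuple[SessionPair, GroundTruth]]:
    """Generate ``n_sessions`` independent corrupted session pairs.

    Per-session seeds derive deterministically from the profile's master
    seed (master + session index, with separate generation and
    corruption streams), so the same master seed reproduces the cohort
    bit-for-bit.
    """
    if n_sessions < 1:
        raise ValidationError("n_sessions must be >= 1")
    profile = profile or SessionProfile()
    cfg = cfg or CorruptionConfig()
    lexicon = lexicon or build_phq9_lexicon()
    cohort = []
    for i in range(n_sessions):
        session_seed = profile.seed + i
        p_i = replace(profile, seed=session_seed)
        c_i = replace(cfg, seed=session_seed)
        ref = generate_reference_session(p_i, lexicon, session_id=f"synthetic-{i:04d}")
        hyp, truth = corrupt_session(ref, c_i, lexicon, vocabulary=profile.vocabulary)
        cohort.append((pair_sessions(ref, hyp, mode=mode), truth))
    return cohort


def write_cohort(
    cohort: Sequence[tuple[SessionPair, GroundTruth]], outdir: str | Path
) -> None:
    """Write a cohort as TSV transcript pairs plus ground-truth JSON."""
    outdir = Path(outdir)
    (outdir / "reference").mkdir(parents=True, exist_ok=True)
    (outdir / "hypothesis").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    for pair, truth in cohort:
        sid = pair.session_id
        write_transcript(pair.reference, outdir / "reference" / f"{sid}.tsv")
        write_transcript(pair.hypothesis, outdir / "hypothesis" / f"{sid}.tsv")
        doc = {
            "session_id": sid,
            "injected_S": truth.injected_S,
            "injected_D": truth.injected_D,
            "injected_I": truth.injected_I,
            "n_ref_tokens": truth.n_ref_tokens,
            "injected_error_rate": truth.injected_error_rate,
            "keyword_outcomes": [
                {
                    "start": k.start,
                    "end": k.end,
                    "keyword": " ".join(k.keyword),
                    "category_id": k.category_id,
                    "transcribed": k.transcribed,
                }
                for k in truth.keyword_outcomes
            ],
        }
        with open(outdir / "truth" / f"{sid}.json", "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
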