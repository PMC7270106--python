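"""Word error rate per unit, per speaker, per session and aggregated.

WER = (S + D + I) / N from a minimum-cost word alignment: substitutions,
deletions and insertions over the reference word count N.  Exact surface
match is required — homophones count as substitutions.  WER can exceed 1
when the hypothesis inserts heavily.

Session-level WER pools S, D, I, N over all units ("divided by the total
number of words") rather than averaging per-utterance ratios, which would
over-weight short utterances; the averaged variant is available behind a
flag for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .alignment import Alignment
from .errors import EmptyGroupError, UndefinedMetricError, ValidationError
from .transcripts import SessionPair, Speaker

__all__ = [
    "WerResult",
    "MetricSummary",
    "compute_wer",
    "pool_wer",
    "session_wer",
    "speaker_wer",
    "unit_wers",
    "summarize_metric",
    "percent",
]


def percent(x: float) -> int:
    """Round a proportion to the nearest integer percent (half-up)."""
    return int(np.floor(100.0 * x + 0.5))


@dataclass(frozen=True)
class WerResult:
    S: int
    D: int
    I: int
    N: int

    @property
    def wer(self) -> float:
        if self.N == 0:
            return 0.0
        return (self.S + self.D + self.I) / self.N

    @property
    def errors(self) -> int:
        return self.S + self.D + self.I


@dataclass(frozen=True)
class MetricSummary:
    """Five-number style summary used in the report tables.

    ``sd`` is the sample standard deviation (n−1 denominator); for a
    single observation it is reported as 0.0 with ``sd_defined=False``.
    """

    n: int
    mean: float
    median: float
    sd: float
    min: float
    max: float
    sd_defined: bool = True


def compute_wer(a: Union[Alignment, WerResult]) -> WerResult:
    """WER from an alignment's S/D/I/N counts.

    N = 0 with an empty hypothesis is a perfect (0.0) transcription of
    silence; N = 0 with a nonempty hypothesis leaves WER undefined.
    """
    S, D, I, N = a.S, a.D, a.I, a.N
    hyp_len = a.hyp_len if isinstance(a, Alignment) else None
    if N == 0 and (I > 0 or (hyp_len or 0) > 0):
        raise UndefinedMetricError("WER undefined: empty reference, nonempty hypothesis")
    return WerResult(S=S, D=D, I=I, N=N)


def pool_wer(alignments: Iterable[Union[Alignment, WerResult]]) -> WerResult:
    """Pool S, D, I, N counts over units and derive one WER."""
    S = D = I = N = 0
    for a in alignments:
        S, D, I, N = S + a.S, D + a.D, I + a.I, N + a.N
    return WerResult(S=S, D=D, I=I, N=N)


def session_wer(pair: SessionPair, averaged: bool = False) -> WerResult | float:
    """Session WER pooled over all units (default) or, with
    ``averaged=True``, the unweighted mean of per-unit WERs."""
    alignments = pair.unit_alignments()
    if averaged:
        vals = [compute_wer(a).wer for a in alignments if a.N > 0]
        if not vals:
            raise EmptyGroupError("no units with reference words")
        return float(np.mean(vals))
    return pool_wer(alignments)


def speaker_wer(pair: SessionPair, speaker: Union[str, Speaker]) -> WerResult:
    """WER pooled over the units whose reference utterance has ``speaker``."""
    sp = Speaker.coerce(speaker)
    alignments = [
        a for u, a in zip(pair.units, pair.unit_alignments()) if u.speaker is sp
    ]
    if not alignments:
        raise EmptyGroupError(f"no units for speaker {sp.value!r} in {pair.session_id!r}")
    return pool_wer(alignments)


def unit_wers(pair: SessionPair) -> list[WerResult]:
    """Per-unit WER results, in unit order (units with N=0 and an empty
    hypothesis report 0)."""
    return [compute_wer(a) for a in pair.unit_alignments()]


def summarize_metric(values: Sequence[float]) -> MetricSummary:
    """Mean, mid-interpolated median, sample SD, min and max."""
    if len(values) == 0:
        raise ValidationError("cannot summarize an empty list")
    arr = np.asarray(values, dtype=float)
    if arr.size == 1:
        v = float(arr[0])
        return MetricSummary(n=1, mean=v, median=v, sd=0.0, min=v, max=v, sd_defined=False)
    return MetricSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        sd=float(arr.std(ddof=1)),
        min=float(arr.min()),
        max=float(arr.max()),
    )
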