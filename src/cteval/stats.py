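"""Harm-phrase subset evaluation and the group-comparison procedure.

Harm-related utterances (self-harm or harm to others, annotated by a
clinician) are a small but safety-critical subset; they are evaluated
with the same WER and semantic-distance machinery and compared against
the rest of the corpus.

Group comparisons follow a normality-gated two-sample procedure: each
group is screened with the Shapiro–Wilk test (gate α = 0.05) and the
Levene test for equal variances is recorded; if both groups look normal
the two-tailed Welch's t-test is used (Welch tolerates unequal
variances, so Levene's result does not switch tests), otherwise the
two-tailed Mann–Whitney U-test.  Significance is declared at α = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .errors import AnnotationError, ValidationError
from .semantic import EmbeddingTable, emd_distance
from .transcripts import SessionPair, Speaker, Unit
from .wer import MetricSummary, compute_wer, summarize_metric

__all__ = [
    "HarmAnnotation",
    "HarmUnit",
    "SubsetReport",
    "NormalityResult",
    "GroupComparison",
    "load_annotations",
    "select_harm_subset",
    "subset_report",
    "normality_gate",
    "compare_groups",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class HarmAnnotation:
    session_id: str
    utterance_index: int
    speaker: Speaker


@dataclass(frozen=True)
class HarmUnit:
    """An annotated unit ready for WER and semantic evaluation."""

    session_id: str
    utterance_index: int
    unit: Unit


def load_annotations(source: Union[str, Path, IO[str]]) -> list[HarmAnnotation]:
    """Read annotations from TSV: ``session_id<TAB>utterance_index<TAB>speaker``."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    out = []
    for line_no, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise AnnotationError(
                f"line {line_no}: expected session_id<TAB>utterance_index<TAB>speaker"
            )
        try:
            idx = int(parts[1])
        except ValueError as exc:
            raise AnnotationError(f"line {line_no}: bad utterance index {parts[1]!r}") from exc
        out.append(HarmAnnotation(parts[0], idx, Speaker.coerce(parts[2])))
    return out


def select_harm_subset(
    pairs: Iterable[SessionPair], annotations: Iterable[HarmAnnotation]
) -> list[HarmUnit]:
    """Resolve annotations to their evaluable units.

    Raises :class:`AnnotationError` naming any annotation that points at
    a missing session or utterance.
    """
    by_id = {p.session_id: p for p in pairs}
    subset = []
    for ann in annotations:
        pair = by_id.get(ann.session_id)
        if pair is None:
            raise AnnotationError(f"annotation references unknown session {ann.session_id!r}")
        unit = next(
            (u for u in pair.units if ann.utterance_index in u.ref_indices), None
        )
        if unit is None:
            raise AnnotationError(
                f"annotation references utterance {ann.utterance_index} "
                f"not present in session {ann.session_id!r}"
            )
        subset.append(HarmUnit(ann.session_id, ann.utterance_index, unit))
    return subset


@dataclass(frozen=True)
class SubsetReport:
    wer: MetricSummary
    semantic: Optional[MetricSummary]
    by_speaker: Mapping[str, dict]
    n_units: int


def subset_report(
    subset: Sequence[HarmUnit], table: Optional[EmbeddingTable] = None
) -> SubsetReport:
    """Per-unit WER and (if a table is given) EMD over an annotated
    subset, summarized overall and per speaker."""
    if not subset:
        raise ValidationError("empty harm subset")
    from .alignment import align_words  # local import to keep module deps flat

    wers: list[float] = []
    dists: list[float] = []
    per_speaker: dict[str, dict[str, list[float]]] = {}
    for hu in subset:
        u = hu.unit
        w = compute_wer(align_words(u.ref_tokens, u.hyp_tokens)).wer
        wers.append(w)
        bucket = per_speaker.setdefault(u.speaker.value, {"wer": [], "semantic": []})
        bucket["wer"].append(w)
        if table is not None:
            d = emd_distance(u.ref_tokens, u.hyp_tokens, table)
            dists.append(d)
            bucket["semantic"].append(d)
    by_speaker = {
        sp: {
            "wer": summarize_metric(vals["wer"]),
            "semantic": summarize_metric(vals["semantic"]) if vals["semantic"] else None,
        }
        for sp, vals in per_speaker.items()
    }
    return SubsetReport(
        wer=summarize_metric(wers),
        semantic=summarize_metric(dists) if dists else None,
        by_speaker=by_speaker,
        n_units=len(subset),
    )


@dataclass(frozen=True)
class NormalityResult:
    p_value: Optional[float]
    is_normal: Optional[bool]  # None when the test is not applicable
    alpha: float = NORMALITY_ALPHA


def normality_gate(values: Sequence[float], alpha: float = NORMALITY_ALPHA) -> NormalityResult:
    """Shapiro–Wilk screen: ``is_normal`` when p ≥ alpha.

    Requires n ≥ 3.  A constant-valued sample is degenerate for the
    test; it is reported as non-testable (``p_value=None``).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValidationError(f"Shapiro–Wilk needs n >= 3, got {arr.size}")
    if np.ptp(arr) == 0.0:
        return NormalityResult(p_value=None, is_normal=None, alpha=alpha)
    stat, p = sps.shapiro(arr)
    return NormalityResult(p_value=float(p), is_normal=bool(p >= alpha), alpha=alpha)


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple[str, str]
    n_a: int
    n_b: int
    normality_p_a: Optional[float]
    normality_p_b: Optional[float]
    variance_p: Optional[float]
    chosen_test: str  # "welch_t" | "mann_whitney"
    statistic: float
    p_value: float
    alpha: float
    significant: bool


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.01,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Normality-gated two-sample comparison.

    Both groups need n ≥ 3.  The Shapiro–Wilk gate decides the test:
    Welch's t when both groups pass, Mann–Whitney U otherwise (including
    when a degenerate group makes the gate untestable).  Levene's p is
    recorded for the report but does not switch tests, since Welch's t
    already tolerates unequal variances.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 3 or xb.size < 3:
        raise ValidationError(f"both groups need n >= 3, got {xa.size} and {xb.size}")
    ga = normality_gate(xa)
    gb = normality_gate(xb)
    if np.ptp(xa) == 0.0 and np.ptp(xb) == 0.0:
        variance_p = None
    else:
        variance_p = float(sps.levene(xa, xb).pvalue)
    if np.ptp(np.concatenate([xa, xb])) == 0.0:
        # every observation identical in both groups: no evidence of any
        # difference, and neither test statistic is defined
        return GroupComparison(
            group_labels=labels,
            n_a=int(xa.size),
            n_b=int(xb.size),
            normality_p_a=ga.p_value,
            normality_p_b=gb.p_value,
            variance_p=variance_p,
            chosen_test="mann_whitney",
            statistic=float(xa.size * xb.size / 2.0),
            p_value=1.0,
            alpha=alpha,
            significant=False,
        )
    both_normal = ga.is_normal is True and gb.is_normal is True
    if both_normal:
        res = sps.ttest_ind(xa, xb, equal_var=False)
        chosen = "welch_t"
    else:
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        chosen = "mann_whitney"
    p = float(res.pvalue)
    return GroupComparison(
        group_labels=labels,
        n_a=int(xa.size),
        n_b=int(xb.size),
        normality_p_a=ga.p_value,
        normality_p_b=gb.p_value,
        variance_p=variance_p,
        chosen_test=chosen,
        statistic=float(res.statistic),
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
    )
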