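"""PHQ-9 keyword lexicon and keyword-level transcription accuracy.

Each of the nine items of the Patient Health Questionnaire (the standard
depression screen) defines a category of clinically relevant keywords
(e.g. item 9: dead, death, depression, died, suicide).  Keyword
occurrences in the human reference transcript are treated as positive
examples; a keyword is a true positive when the ASR hypothesis
transcribed it exactly (every token of the span is an alignment match),
a false negative otherwise, and a hypothesis keyword with no identical
reference counterpart is a false positive.  Sensitivity (recall) and
positive predictive value (precision) are reported per keyword, per
category, and as a weighted average over pooled counts.

Specificity is computable (negatives are all non-keyword words, so true
negatives dominate) but is intentionally not part of the reports: with
realistic corpora it sits above 99.9% for every keyword and does not
differentiate performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import yaml

from .errors import ValidationError
from .transcripts import SessionPair, normalize_tokens
from .wer import percent

__all__ = [
    "KeywordCategory",
    "KeywordLexicon",
    "KeywordSpan",
    "KeywordConfusion",
    "build_phq9_lexicon",
    "load_lexicon",
    "find_keyword_spans",
    "classify_keyword_outcomes",
    "category_confusions",
    "confusion_metrics",
    "aggregate_categories",
    "specificity",
]


@dataclass(frozen=True)
class KeywordCategory:
    category_id: int
    label: str
    keywords: tuple[tuple[str, ...], ...]  # normalized token sequences


@dataclass(frozen=True)
class KeywordLexicon:
    categories: tuple[KeywordCategory, ...]

    def __post_init__(self) -> None:
        ids = [c.category_id for c in self.categories]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate category ids: {ids}")

    def all_keywords(self) -> list[tuple[tuple[str, ...], int]]:
        """All (keyword tokens, category id) pairs."""
        return [(kw, c.category_id) for c in self.categories for kw in c.keywords]

    def category(self, category_id: int) -> KeywordCategory:
        for c in self.categories:
            if c.category_id == category_id:
                return c
        raise KeyError(category_id)


def _lexicon_from_doc(doc) -> KeywordLexicon:
    cats = []
    for entry in doc["categories"]:
        keywords = tuple(
            tuple(normalize_tokens(str(kw))) for kw in entry["keywords"]
        )
        if any(len(kw) == 0 for kw in keywords):
            raise ValidationError(f"category {entry['id']}: empty keyword after normalization")
        cats.append(
            KeywordCategory(
                category_id=int(entry["id"]),
                label=str(entry.get("label", "")),
                keywords=keywords,
            )
        )
    return KeywordLexicon(categories=tuple(cats))


def build_phq9_lexicon() -> KeywordLexicon:
    """The frozen nine-category PHQ-9 keyword lexicon shipped as data."""
    text = resources.files("cteval.data").joinpath("phq9_lexicon.yaml").read_text("utf-8")
    return _lexicon_from_doc(yaml.safe_load(text))


def load_lexicon(source: Union[str, Path, IO[str]]) -> KeywordLexicon:
    """Load a lexicon override from a YAML file with the same layout as
    the shipped PHQ-9 file (``categories: [{id, label, keywords}]``)."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    return _lexicon_from_doc(doc)


@dataclass(frozen=True)
class KeywordSpan:
    start: int
    end: int  # half-open token span
    keyword: tuple[str, ...]
    category_id: int


def find_keyword_spans(tokens: Sequence[str], lex: KeywordLexicon) -> list[KeywordSpan]:
    """All maximal non-overlapping keyword matches, longest-first at each
    position; spans are half-open ``[start, end)``."""
    by_first: dict[str, list[tuple[tuple[str, ...], int]]] = {}
    for kw, cid in lex.all_keywords():
        by_first.setdefault(kw[0], []).append((kw, cid))
    for lst in by_first.values():
        lst.sort(key=lambda e: len(e[0]), reverse=True)
    spans: list[KeywordSpan] = []
    i, n = 0, len(tokens)
    while i < n:
        hit = None
        for kw, cid in by_first.get(tokens[i], ()):
            if tuple(tokens[i : i + len(kw)]) == kw:
                hit = KeywordSpan(i, i + len(kw), kw, cid)
                break  # longest first
        if hit is not None:
            spans.append(hit)
            i = hit.end
        else:
            i += 1
    return spans


@dataclass(frozen=True)
class KeywordConfusion:
    """TP/FN/FP counts with derived integer-percent sensitivity and PPV.

    ``scope`` is ``"keyword"``, ``"category"`` or ``"weighted_average"``;
    ``n_positives == TP + FN`` (reference occurrences).  A zero
    denominator leaves the percentage ``None`` (undefined), never 0.
    """

    scope: str
    name: str
    TP: int
    FN: int
    FP: int
    category_id: Optional[int] = None

    @property
    def n_positives(self) -> int:
        return self.TP + self.FN

    @property
    def sensitivity_pct(self) -> Optional[int]:
        return confusion_metrics(self.TP, self.FN, self.FP)["sensitivity_pct"]

    @property
    def ppv_pct(self) -> Optional[int]:
        return confusion_metrics(self.TP, self.FN, self.FP)["ppv_pct"]


def confusion_metrics(TP: int, FN: int, FP: int) -> dict[str, Optional[int]]:
    """Sensitivity = TP/(TP+FN) and PPV = TP/(TP+FP), rounded half-up to
    integer percent; undefined (``None``) on a zero denominator."""
    sens = percent(TP / (TP + FN)) if TP + FN > 0 else None
    ppv = percent(TP / (TP + FP)) if TP + FP > 0 else None
    return {"sensitivity_pct": sens, "ppv_pct": ppv}


def _pair_outcomes(pair: SessionPair, lex: KeywordLexicon):
    """Yield (keyword, category_id, outcome) for one session pair, where
    outcome is 'TP', 'FN' or 'FP'."""
    for unit, alignment in zip(pair.units, pair.unit_alignments()):
        ref_match = [False] * len(unit.ref_tokens)
        hyp_match_ref: dict[int, int] = {}  # hyp idx -> ref idx, match ops only
        for op in alignment.ops:
            if op.kind == "match":
                ref_match[op.ref_index] = True
                hyp_match_ref[op.hyp_index] = op.ref_index
        ref_spans = find_keyword_spans(unit.ref_tokens, lex)
        ref_span_set = {(s.start, s.end, s.keyword) for s in ref_spans}
        for s in ref_spans:
            ok = all(ref_match[s.start : s.end])
            yield s.keyword, s.category_id, ("TP" if ok else "FN")
        for s in find_keyword_spans(unit.hyp_tokens, lex):
            refs = [hyp_match_ref.get(j) for j in range(s.start, s.end)]
            if None not in refs:
                lo, hi = refs[0], refs[-1] + 1
                if refs == list(range(lo, hi)) and (lo, hi, s.keyword) in ref_span_set:
                    continue  # faithful transcription, already counted TP
            yield s.keyword, s.category_id, "FP"


def classify_keyword_outcomes(
    pairs: Union[SessionPair, Iterable[SessionPair]], lex: Optional[KeywordLexicon] = None
) -> list[KeywordConfusion]:
    """Per-keyword TP/FN/FP counts pooled over one or more session pairs.

    A reference keyword span is TP only when every one of its tokens is
    an alignment match (multiword spans must be fully transcribed);
    otherwise FN.  A hypothesis keyword span that is not an exact match
    of an identical reference span is FP — so a substitution that turns
    keyword A into keyword B yields FN(A) and FP(B).
    """
    lex = lex or build_phq9_lexicon()
    if isinstance(pairs, SessionPair):
        pairs = [pairs]
    counts: dict[tuple[str, ...], dict[str, int]] = {}
    cat_of: dict[tuple[str, ...], int] = {}
    for kw, cid in lex.all_keywords():
        counts[kw] = {"TP": 0, "FN": 0, "FP": 0}
        cat_of[kw] = cid
    for pair in pairs:
        for kw, cid, outcome in _pair_outcomes(pair, lex):
            counts[kw][outcome] += 1
    return [
        KeywordConfusion(
            scope="keyword",
            name=" ".join(kw),
            TP=c["TP"],
            FN=c["FN"],
            FP=c["FP"],
            category_id=cat_of[kw],
        )
        for kw, c in counts.items()
    ]


def category_confusions(
    keyword_confusions: Sequence[KeywordConfusion], lex: Optional[KeywordLexicon] = None
) -> list[KeywordConfusion]:
    """Pool per-keyword counts into the nine per-category rows."""
    lex = lex or build_phq9_lexicon()
    out = []
    for cat in lex.categories:
        members = [c for c in keyword_confusions if c.category_id == cat.category_id]
        out.append(
            KeywordConfusion(
                scope="category",
                name=cat.label,
                TP=sum(c.TP for c in members),
                FN=sum(c.FN for c in members),
                FP=sum(c.FP for c in members),
                category_id=cat.category_id,
            )
        )
    return out


def aggregate_categories(confusions: Sequence[KeywordConfusion]) -> KeywordConfusion:
    """Weighted-average row: pool TP/FN/FP across categories first, then
    derive the percentages from the pooled counts (this is not the mean
    of the per-category percentages)."""
    if not confusions:
        raise ValidationError("nothing to aggregate")
    return KeywordConfusion(
        scope="weighted_average",
        name="weighted average",
        TP=sum(c.TP for c in confusions),
        FN=sum(c.FN for c in confusions),
        FP=sum(c.FP for c in confusions),
    )


def specificity(
    pairs: Union[SessionPair, Iterable[SessionPair]], lex: Optional[KeywordLexicon] = None
) -> float:
    """Overall keyword specificity TN/(TN+FP), with negatives = reference
    words not inside any keyword span.  Reported nowhere in the tables —
    on realistic corpora it exceeds 0.999 for every keyword and carries
    no signal — but exposed for verification."""
    lex = lex or build_phq9_lexicon()
    if isinstance(pairs, SessionPair):
        pairs = [pairs]
    pairs = list(pairs)
    confusions = classify_keyword_outcomes(pairs, lex)
    fp = sum(c.FP for c in confusions)
    negatives = 0
    for pair in pairs:
        for unit in pair.units:
            spans = find_keyword_spans(unit.ref_tokens, lex)
            keyword_tokens = sum(s.end - s.start for s in spans)
            negatives += len(unit.ref_tokens) - keyword_tokens
    if negatives == 0:
        raise ValidationError("no negative examples in corpus")
    tn = max(negatives - fp, 0)
    return tn / (tn + fp)
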