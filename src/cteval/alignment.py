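"""Minimum-cost word-level alignment between token sequences.

The alignment is the classic Levenshtein edit script over words with unit
costs for substitution, deletion and insertion.  It is the basis of the
word error rate WER = (S + D + I) / N, where N is the reference length,
and of the keyword-level true/false-positive accounting: a reference word
is "correctly transcribed" exactly when the alignment pairs it with an
identical hypothesis word (homophones and near-misses count as errors).

The backtrace is deterministic: when several optimal edit scripts exist
the trace prefers match > substitution > deletion > insertion, so op logs
are reproducible.  The total cost S + D + I is invariant to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["AlignOp", "Alignment", "align_words", "word_edit_distance"]

# above this size the cost matrix is filled with vectorised numpy rows;
# below it a plain python DP has less overhead
_NUMPY_THRESHOLD = 64


@dataclass(frozen=True)
class AlignOp:
    """One step of the edit script.

    ``match`` and ``substitution`` carry both indices; ``deletion`` only
    ``ref_index``; ``insertion`` only ``hyp_index``.
    """

    kind: str  # "match" | "substitution" | "deletion" | "insertion"
    ref_index: Optional[int] = None
    hyp_index: Optional[int] = None


@dataclass(frozen=True)
class Alignment:
    """A monotone word alignment with its error counts.

    Invariants: ``S + D + matches == N`` (reference length) and
    ``S + I + matches == hyp_len``; ``S + D + I`` equals the word-level
    Levenshtein distance.
    """

    ops: tuple[AlignOp, ...]
    S: int
    D: int
    I: int
    N: int
    matches: int

    @property
    def cost(self) -> int:
        return self.S + self.D + self.I

    @property
    def hyp_len(self) -> int:
        return self.S + self.I + self.matches


def _cost_matrix_python(ref_ids: Sequence[int], hyp_ids: Sequence[int]) -> list[list[int]]:
    n, m = len(ref_ids), len(hyp_ids)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    D[0] = list(range(m + 1))
    for i in range(1, n + 1):
        row, prev = D[i], D[i - 1]
        row[0] = i
        ri = ref_ids[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (ri != hyp_ids[j - 1])
            row[j] = min(sub, prev[j] + 1, row[j - 1] + 1)
    return D


def _cost_matrix_numpy(ref_ids: np.ndarray, hyp_ids: np.ndarray) -> np.ndarray:
    n, m = len(ref_ids), len(hyp_ids)
    D = np.empty((n + 1, m + 1), dtype=np.int32)
    ar = np.arange(m + 1, dtype=np.int32)
    D[0] = ar
    t = np.empty(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        prev = D[i - 1]
        # candidate costs ignoring insertions (which have a left-to-right
        # dependency): diagonal substitution/match and vertical deletion
        np.minimum(prev[:-1] + (ref_ids[i - 1] != hyp_ids), prev[1:] + 1, out=t[1:])
        t[0] = i
        # fold in insertions: cur[j] = min_{k<=j} t[k] + (j - k)
        D[i] = np.minimum.accumulate(t - ar) + ar
    return D


def _backtrace(D, ref: Sequence, hyp: Sequence) -> tuple[AlignOp, ...]:
    ops: list[AlignOp] = []
    i, j = len(ref), len(hyp)
    while i > 0 or j > 0:
        here = D[i][j]
        if i > 0 and j > 0 and ref[i - 1] == hyp[j - 1] and D[i - 1][j - 1] == here:
            ops.append(AlignOp("match", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and j > 0 and D[i - 1][j - 1] + 1 == here:
            ops.append(AlignOp("substitution", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and D[i - 1][j] + 1 == here:
            ops.append(AlignOp("deletion", i - 1, None))
            i -= 1
        else:
            ops.append(AlignOp("insertion", None, j - 1))
            j -= 1
    ops.reverse()
    return tuple(ops)


def align_words(ref: Sequence[str], hyp: Sequence[str]) -> Alignment:
    """Optimally align two token sequences under unit edit costs.

    Parameters
    ----------
    ref, hyp
        Reference and hypothesis tokens, normalized by the same
        configuration.  Empty sequences are allowed.

    Returns
    -------
    Alignment
        Deterministic optimal edit script with S, D, I counts and
        N = ``len(ref)``.
    """
    ref = list(ref)
    hyp = list(hyp)
    # map tokens to integer ids so comparisons are cheap
    ids: dict[str, int] = {}
    ref_ids = [ids.setdefault(w, len(ids)) for w in ref]
    hyp_ids = [ids.setdefault(w, len(ids)) for w in hyp]
    if max(len(ref), len(hyp)) > _NUMPY_THRESHOLD:
        D = _cost_matrix_numpy(
            np.asarray(ref_ids, dtype=np.int32), np.asarray(hyp_ids, dtype=np.int32)
        )
    else:
        D = _cost_matrix_python(ref_ids, hyp_ids)
    ops = _backtrace(D, ref_ids, hyp_ids)
    s = sum(1 for o in ops if o.kind == "substitution")
    d = sum(1 for o in ops if o.kind == "deletion")
    ins = sum(1 for o in ops if o.kind == "insertion")
    matches = len(ops) - s - d - ins
    return Alignment(ops=ops, S=s, D=d, I=ins, N=len(ref), matches=matches)


def word_edit_distance(ref: Sequence[str], hyp: Sequence[str]) -> int:
    """Word-level Levenshtein distance (S + D + I of the optimal script)."""
    return align_words(ref, hyp).cost
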