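"""Embedding-based semantic distance between reference and hypothesis text.

Word error rate treats every error as equal; transcribing "death" as
"dead" costs as much as transcribing it as "desk".  Semantic distance
instead embeds each sentence's words (word2vec-style vectors, pluggable)
and measures dissimilarity in the embedding space.  Zero distance means
the two sentences use the same in-vocabulary words.

The primary distance is the earth mover (optimal transport) distance
between the two sentences' normalized word-frequency distributions, with
Euclidean distance between word vectors as ground cost — the word-mover
formulation.  The degenerate alternative, Euclidean distance between the
two mean-pooled sentence vectors, and cosine distance of the pooled
vectors are computed alongside, since pooled-vector comparison is the
other common reading of "sentence embedding distance"; for single-word
sentences the earth mover and pooled Euclidean distances coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from .errors import UndefinedMetricError, ValidationError
from .transcripts import SessionPair
from .wer import MetricSummary, summarize_metric

__all__ = [
    "EmbeddingTable",
    "SentenceDistance",
    "SessionSemanticResult",
    "CalibrationResult",
    "mean_pool_embedding",
    "emd_distance",
    "cosine_distance",
    "pooled_euclidean_distance",
    "sentence_distance",
    "session_semantic_distance",
    "calibration_baselines",
    "random_embedding_table",
]


@dataclass
class EmbeddingTable:
    """A word → vector lookup with an out-of-vocabulary policy.

    ``oov_policy="drop"`` (default) ignores out-of-vocabulary words and
    renormalizes; ``"zero"`` substitutes zero vectors (which distorts
    pooled means and is provided for comparison only).
    """

    dimension: int
    vectors: dict[str, np.ndarray]
    oov_policy: str = "drop"

    def __post_init__(self) -> None:
        if self.oov_policy not in ("drop", "zero"):
            raise ValidationError(f"oov_policy must be drop|zero, got {self.oov_policy!r}")
        for w, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.dimension,):
                raise ValidationError(
                    f"vector for {w!r} has shape {v.shape}, expected ({self.dimension},)"
                )
            self.vectors[w] = v

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]

    @property
    def vocabulary(self) -> list[str]:
        return list(self.vectors)

    # -- I/O -----------------------------------------------------------
    @classmethod
    def load_word2vec_text(cls, source: Union[str, Path, IO[str]], oov_policy: str = "drop"):
        """Read the standard word2vec text format: a ``count dim`` header
        line, then one ``word v1 … vd`` line per word."""
        stream, close = _open(source, "r")
        try:
            header = stream.readline().split()
            if len(header) != 2:
                raise ValidationError("word2vec text file must start with 'count dim'")
            count, dim = int(header[0]), int(header[1])
            vectors: dict[str, np.ndarray] = {}
            for line in stream:
                parts = line.rstrip("\n").split(" ")
                if len(parts) < dim + 1:
                    raise ValidationError(f"short embedding line: {line[:50]!r}")
                vectors[parts[0]] = np.asarray(parts[1 : dim + 1], dtype=float)
            if len(vectors) != count:
                raise ValidationError(f"header declared {count} words, found {len(vectors)}")
            return cls(dimension=dim, vectors=vectors, oov_policy=oov_policy)
        finally:
            if close:
                stream.close()

    def save_word2vec_text(self, target: Union[str, Path, IO[str]]) -> None:
        stream, close = _open(target, "w")
        try:
            stream.write(f"{len(self.vectors)} {self.dimension}\n")
            for w, v in self.vectors.items():
                stream.write(w + " " + " ".join(repr(float(x)) for x in v) + "\n")
        finally:
            if close:
                stream.close()

    @classmethod
    def load_tsv(cls, source: Union[str, Path, IO[str]], oov_policy: str = "drop"):
        """Read a two-column TSV: ``word<TAB>v1 v2 … vd``."""
        stream, close = _open(source, "r")
        try:
            vectors: dict[str, np.ndarray] = {}
            dim = None
            for line_no, line in enumerate(stream, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ValidationError(f"line {line_no}: expected word<TAB>values")
                vec = np.asarray(parts[1].split(), dtype=float)
                if dim is None:
                    dim = vec.size
                elif vec.size != dim:
                    raise ValidationError(f"line {line_no}: dimension {vec.size} != {dim}")
                vectors[parts[0]] = vec
            if dim is None:
                raise ValidationError("empty embedding TSV")
            return cls(dimension=int(dim), vectors=vectors, oov_policy=oov_policy)
        finally:
            if close:
                stream.close()


def _open(source, mode):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def random_embedding_table(
    words: Iterable[str], dimension: int = 50, seed: int = 0, oov_policy: str = "drop"
) -> EmbeddingTable:
    """Deterministic random table (standard normal / sqrt(dim) entries)
    for simulation and testing; fixed seed ⇒ identical vectors."""
    words = list(words)
    rng = np.random.default_rng(seed)
    mat = rng.standard_normal((len(words), dimension)) / np.sqrt(dimension)
    return EmbeddingTable(
        dimension=dimension,
        vectors={w: mat[i] for i, w in enumerate(words)},
        oov_policy=oov_policy,
    )


# ---------------------------------------------------------------------------


def _in_vocab(tokens: Sequence[str], table: EmbeddingTable) -> list[str]:
    return [t for t in tokens if t in table]


def mean_pool_embedding(tokens: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Arithmetic mean of the word vectors of ``tokens``.

    Under the drop policy only in-vocabulary words enter the mean (all
    OOV → :class:`UndefinedMetricError`); under the zero policy OOV words
    contribute zero vectors but still count in the denominator.
    """
    if table.oov_policy == "drop":
        used = _in_vocab(tokens, table)
        if not used:
            raise UndefinedMetricError("all tokens out of vocabulary under drop policy")
        return np.mean([table[t] for t in used], axis=0)
    if len(tokens) == 0:
        raise UndefinedMetricError("cannot pool an empty token list")
    zero = np.zeros(table.dimension)
    return np.mean([table[t] if t in table else zero for t in tokens], axis=0)


def _bow(tokens: Sequence[str], table: EmbeddingTable, uniform: bool):
    """Unique in-vocabulary types, their normalized weights, and vectors."""
    used = _in_vocab(tokens, table)
    if not used:
        raise UndefinedMetricError("no in-vocabulary tokens")
    types: dict[str, int] = {}
    for t in used:
        types[t] = types.get(t, 0) + 1
    words = list(types)
    if uniform:
        w = np.full(len(words), 1.0 / len(words))
    else:
        w = np.asarray([types[t] for t in words], dtype=float)
        w /= w.sum()
    vecs = np.stack([table[t] for t in words])
    return words, w, vecs


def emd_distance(
    ref: Sequence[str],
    hyp: Sequence[str],
    table: EmbeddingTable,
    *,
    uniform_weights: bool = False,
) -> float:
    """Earth mover distance between two sentences' word distributions.

    Solves the discrete optimal-transport linear program between the
    normalized word-frequency distributions of the two sentences
    (``uniform_weights=True`` switches to uniform weight per unique
    type), with pairwise Euclidean distance between word vectors as
    ground cost.  Identical in-vocabulary multisets give exactly 0.
    """
    rw, ra, rv = _bow(ref, table, uniform_weights)
    hw, hb, hv = _bow(hyp, table, uniform_weights)
    if dict(zip(rw, ra)) == dict(zip(hw, hb)):
        return 0.0  # identical distributions: exactly zero, skip the LP
    cost = cdist(rv, hv)  # euclidean
    m, n = cost.shape
    if m == 1:
        return float(cost[0] @ hb)
    if n == 1:
        return float(ra @ cost[:, 0])
    # transport LP: minimize <cost, X> s.t. row sums = ra, col sums = hb
    c = cost.ravel()
    A = []
    b = []
    for i in range(m):
        row = np.zeros(m * n)
        row[i * n : (i + 1) * n] = 1.0
        A.append(row)
        b.append(ra[i])
    for j in range(n - 1):  # last column constraint is redundant
        col = np.zeros(m * n)
        col[j::n] = 1.0
        A.append(col)
        b.append(hb[j])
    res = linprog(c, A_eq=np.asarray(A), b_eq=np.asarray(b), bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - tiny dense LPs always solve
        raise UndefinedMetricError(f"transport LP failed: {res.message}")
    return float(max(res.fun, 0.0))


def pooled_euclidean_distance(
    ref: Sequence[str], hyp: Sequence[str], table: EmbeddingTable
) -> float:
    """Euclidean distance between the two mean-pooled sentence vectors."""
    return float(np.linalg.norm(mean_pool_embedding(ref, table) - mean_pool_embedding(hyp, table)))


def cosine_distance(ref: Sequence[str], hyp: Sequence[str], table: EmbeddingTable) -> float:
    """1 − cosine similarity of the mean-pooled sentence vectors, in [0, 2]."""
    a = mean_pool_embedding(ref, table)
    b = mean_pool_embedding(hyp, table)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedMetricError("cosine distance undefined for a zero-norm embedding")
    return float(np.clip(1.0 - (a @ b) / (na * nb), 0.0, 2.0))


@dataclass(frozen=True)
class SentenceDistance:
    emd: float
    pooled_euclidean: float
    cosine: float
    n_ref_tokens_used: int
    n_hyp_tokens_used: int


def sentence_distance(
    ref: Sequence[str], hyp: Sequence[str], table: EmbeddingTable
) -> SentenceDistance:
    """All three sentence-level distances for one reference/hypothesis pair."""
    return SentenceDistance(
        emd=emd_distance(ref, hyp, table),
        pooled_euclidean=pooled_euclidean_distance(ref, hyp, table),
        cosine=cosine_distance(ref, hyp, table),
        n_ref_tokens_used=len(_in_vocab(ref, table)),
        n_hyp_tokens_used=len(_in_vocab(hyp, table)),
    )


@dataclass(frozen=True)
class SessionSemanticResult:
    summary: MetricSummary
    distances: tuple[float, ...]  # per computable unit, in unit order
    n_excluded: int  # units with no in-vocabulary tokens on a side


def session_semantic_distance(pair: SessionPair, table: EmbeddingTable) -> SessionSemanticResult:
    """Per-unit earth mover distances for a session, summarized.

    Units where either side has no in-vocabulary token are excluded from
    the summary and counted in ``n_excluded``.
    """
    distances: list[float] = []
    excluded = 0
    for u in pair.units:
        try:
            distances.append(emd_distance(u.ref_tokens, u.hyp_tokens, table))
        except UndefinedMetricError:
            excluded += 1
    if not distances:
        raise UndefinedMetricError(
            f"no unit in session {pair.session_id!r} has a computable distance"
        )
    return SessionSemanticResult(
        summary=summarize_metric(distances), distances=tuple(distances), n_excluded=excluded
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Interpretation anchors for the distance scale: how far apart are
    random word pairs, random sentence pairs, and true paraphrases under
    the supplied embedding table."""

    random_word_distance: float
    random_sentence_distance: float
    paraphrase_distance: Optional[float]
    n_samples: int
    seed: int


def calibration_baselines(
    table: EmbeddingTable,
    corpus: Sequence[Sequence[str]],
    paraphrases: Sequence[tuple[Sequence[str], Sequence[str]]] = (),
    n_samples: int = 200,
    seed: int = 0,
) -> CalibrationResult:
    """Mean EMD over random word pairs, random sentence pairs (distinct
    corpus indices) and supplied paraphrase pairs; deterministic under a
    fixed seed.  With an empty paraphrase list that field is ``None``."""
    rng = np.random.default_rng(seed)
    vocab = [w for w in table.vocabulary]
    if not vocab:
        raise ValidationError("empty embedding table")
    word_vals = []
    for _ in range(n_samples):
        if len(vocab) == 1:
            a = b = vocab[0]
        else:
            i, j = rng.choice(len(vocab), size=2, replace=False)
            a, b = vocab[int(i)], vocab[int(j)]
        word_vals.append(emd_distance([a], [b], table))
    usable = [s for s in corpus if _in_vocab(s, table)]
    if len(usable) < 2:
        raise ValidationError("corpus must contain at least two embeddable sentences")
    sent_vals = []
    for _ in range(n_samples):
        i, j = rng.choice(len(usable), size=2, replace=False)
        sent_vals.append(emd_distance(usable[int(i)], usable[int(j)], table))
    para = None
    if paraphrases:
        para = float(np.mean([emd_distance(a, b, table) for a, b in paraphrases]))
    return CalibrationResult(
        random_word_distance=float(np.mean(word_vals)),
        random_sentence_distance=float(np.mean(sent_vals)),
        paraphrase_distance=para,
        n_samples=n_samples,
        seed=seed,
    )
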