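# Methods

This note records the models, conventions and numerical choices behind
`cteval`, in the spirit of a statistics package's model documentation:
what is computed, under which assumptions, and what the synthetic
experiments do and do not establish.

## Transcript model and normalization

A session is an ordered list of utterances, each a contiguous
single-speaker stretch with an optional start time in seconds
(non-decreasing where present). Speakers are a three-way enum
(therapist / patient / unknown); labels outside the first two map to
unknown rather than erroring, since scribes do mark unattributable
speech. Tokenization lowercases, strips punctuation except intra-word
apostrophes and hyphens (`i'm`, `mm-hm`), keeps numerals as written, and
keeps filler words by default because human scribes transcribe them
verbatim; a flag drops a small filler list for sensitivity analysis.
Normalization is idempotent, and both transcripts of a pair must use the
same configuration — WER is meaningless across mismatched tokenizers.

**Pairing.** Evaluation units are reference utterances. Two modes carve
the hypothesis token stream into units:

* `global_align` (default): one word-level alignment of the full token
  streams; each matched/substituted hypothesis token inherits its
  reference partner's utterance, insertions join the next anchored
  token's utterance. This is the right default for commodity ASR output,
  which arrives undiarized and untimed. Because unit boundaries are cut
  from a globally optimal script, the sum of per-unit optimal costs
  equals the global optimum, so per-unit WERs pool consistently.
* `timestamp`: hypothesis word times (linearly interpolated inside each
  hypothesis utterance; the final utterance extrapolates at 2.5 words/s,
  i.e. ~150 words/min conversational rate) are binned into reference
  utterance windows `[start_i, start_{i+1})`. This reproduces
  timing-based evaluation when transcriptionist timestamps exist, with
  the caveat that human timestamps carry reaction-time error.

Whether ASR output should be segmented per utterance or globally is
genuinely open; both modes are first-class rather than guessing.

## Word error rate

`WER = (S + D + I) / N` from a unit-cost Levenshtein alignment over
words. Unit costs are implied by the definition; exact surface match is
required, so homophones count as substitutions. The DP fills the cost
matrix with vectorized rows (insertion's left-to-right dependency is
folded in with a prefix-minimum identity), which keeps a 6,500 × 6,500
session alignment under a second; sequences below 64 tokens use a plain
Python DP with less overhead. The backtrace deterministically prefers
match > substitution > deletion > insertion among equal-cost moves —
S + D + I is invariant to this tie-break, only the op log differs.

Session WER pools S, D, I, N over units rather than averaging
per-utterance ratios, which would up-weight short utterances; the
unweighted average is available behind `averaged=True`. WER of an empty
reference with a nonempty hypothesis is undefined (error), and empty
against empty is 0. WER may exceed 1 under heavy insertion.

## Semantic distance

Word embeddings are a pluggable table (word2vec text format or TSV);
the package never trains embeddings. Out-of-vocabulary policy is
`drop`-and-renormalize by default, because zero-vector imputation drags
pooled means toward the origin; the `zero` policy exists for comparison.

The primary distance is the earth mover distance between the two
sentences' normalized word-frequency distributions with Euclidean
ground cost between word vectors (the word-mover formulation). The
pooled alternative — Euclidean or cosine distance between mean-pooled
sentence vectors — is computed alongside: for two single pooled vectors
the transport problem degenerates to their Euclidean distance, and which
of the two formulations a given study means by "sentence embeddings
compared with earth mover distance" is ambiguous, so both are reported
and neither is claimed as anyone's exact computation. For single-word
sentences they coincide exactly. Weights are within-sentence token
frequencies (not uniform over types); `uniform_weights=True` switches.
Stopwords are not removed. The transport LP is solved with HiGHS via
`scipy.optimize.linprog` (one redundant column constraint dropped);
1×n and m×1 cases short-circuit to closed form. Tests verify the metric
axioms, positive-homogeneity under embedding scaling, and agreement to
1e−6 with an independent brute-force solver that enumerates every
vertex of the transportation polytope (spanning trees of K_{m,n}).

Raw distances are unit-less and table-dependent, so
`calibration_baselines` anchors the scale: mean EMD over random word
pairs, over random distinct-index sentence pairs from a corpus, and over
supplied paraphrase pairs, all seeded. Published corpus-level distance
values depend on an unreleased embedding model and are therefore not
reproduction targets; the anchors make any table interpretable.

## PHQ-9 keyword accounting

The nine-category keyword lexicon is frozen package data (originally
assembled from PHQ-9 terms expanded through the UMLS terminology; the
expansion is represented by the lexicon file interface, not live
queries). Matching is longest-first, non-overlapping, on normalized
tokens. Classification is alignment-based: a reference keyword span is
TP iff every token is a match op (a half-transcribed multiword phrase
fails clinical detection, so partial matches are FN; spans deleted
outright are FN too); a hypothesis keyword span not exactly matching an
identical reference span is FP, so keyword-for-keyword substitutions
count FN(A) + FP(B). Percentages round half-up to integer percent.
Weighted averages pool TP/FN/FP across categories before deriving
percentages — pooling does not commute with averaging percentages, and
the pooled definition is the one that reproduces published tables from
their counts. Specificity is computable (`specificity()`) but excluded
from reports: negatives are all non-keyword words, so it exceeds 99.9%
on any realistic corpus and differentiates nothing. Zero denominators
report `None`, never 0.

## Harm subset and statistics

Harm annotations are utterance-granular (clinicians annotate sentences;
sub-utterance spans are out of scope) and are input, never inferred.
The subset gets the same per-unit WER/EMD treatment plus per-speaker
summaries.

Group comparisons: Shapiro–Wilk on each group at gate α = 0.05,
Levene's test recorded; Welch's t (two-tailed) when both groups pass
normality, Mann–Whitney U (two-tailed) otherwise. Levene does not
switch tests because Welch's t already tolerates unequal variances —
the gate rule itself is a documented package choice, consistent with
test/distribution pairings seen in practice but not a claim about any
particular study's code. Significance α defaults to 0.01. Degenerate
inputs: constant samples are non-testable for normality (reported
`None`, routed to Mann–Whitney); two all-identical groups return p = 1.
Summary statistics use sample SD (n−1) and mid-interpolated medians; a
single observation reports SD 0 with `sd_defined=False`.

## Synthetic corpus

The generator emulates the session shape of recorded college-counseling
psychotherapy: alternating speaker turns (therapist first), per-speaker
word totals drawn from truncated normals at therapist 2909 ± 1128 and
patient 3665 ± 1550 words (truncation at ≥1 word, by rejection), turn
lengths 1 + Poisson(14) — about 15 words per turn, a plausible
conversational turn length chosen once since turn counts are not
published — and timestamps at 2.5 words/s. The default vocabulary is
5,000 distinct synthetic words (`w0`…`w4999`) disjoint from the keyword
lexicon, so random substitutions essentially never collide with real
words or keywords; keyword injection at per-position rate 0.0016
reproduces roughly a thousand keyword occurrences per hundred sessions.

The error channel is independent per token: substitute with probability
`sub_rate` (from the shipped homophone confusion table when the word has
an entry, else a uniform different vocabulary word), delete with
`del_rate` (mutually exclusive draws, so `sub+del ≤ 1`), and insert a
random word after each position with `ins_rate`. Keyword-span tokens
scale substitution/deletion by `keyword_error_multiplier` (jointly
capped at total probability 1), letting keyword sensitivity be dialled
independently of base WER. Per-session seeds are master seed + session
index, with generation and corruption on separate derived streams, so
cohorts are bit-reproducible.

What the channel deliberately omits: acoustic confusability beyond the
small homophone list, burst/phrase errors, speaker-dependent error
rates, and diarization mistakes (reference diarization is recovered
through pairing). Passing the synthetic recovery tests therefore shows
the *accounting* is correct — measured WER converges to the injected
rate from below (the aligner occasionally merges an adjacent
deletion+insertion into one substitution, so a 20% injected rate
measures ≈ 19.5%), and keyword sensitivity tracks the injected
keyword-survival probability — not that any real ASR system behaves
like the channel.

## Problem sizes and verification

The shipped verification suite uses: exhaustive alignment-oracle
comparison over all ~14.6k sequence pairs of length ≤ 4 on a 3-symbol
alphabet; 500 random transport instances with ≤ 4 unique tokens per
side against the vertex-enumeration oracle (tolerance 1e−6); a
100-session cohort (~650k reference tokens) for WER recovery at
sub/del/ins = 0.10/0.05/0.05 with acceptance band 18.5–20.5%; a
25-session cohort with keyword rate 0.04 and keyword error probability
0.20 (≥ 5,000 injected occurrences) for sensitivity recovery at
80% ± 3 points; and 500 null replicates (two N(0,1) groups, n = 100)
for the statistical gate, requiring ≤ 3% rejections at α = 0.01. The
`edlib` sequence-alignment library provides an additional external
cross-check of alignment costs in the test suite.

## Known limitations

* Corpus-level published headline figures (mean WER, corpus semantic
  distances and their p-values) require the private recordings and the
  original embedding model; the package reproduces the published
  keyword table exactly from its counts and substitutes property-based
  synthetic verification for the rest.
* The TP criterion is exact surface match; stemming or synonym credit
  is intentionally out of scope, as is any live terminology-service
  expansion of the lexicon.
* `timestamp` pairing trusts reference timestamps and interpolates
  hypothesis word times; with sparse or erroneous timestamps,
  `global_align` is the safer mode.
* The TSV dialect cannot carry tabs/newlines inside utterance text
  (writer raises); use the JSON dialect for such content.
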