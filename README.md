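# cteval — clinical transcript evaluation for psychotherapy ASR

`cteval` quantifies how accurately an automatic speech recognition (ASR)
system transcribes psychotherapy sessions, for researchers and digital
mental-health engineers who need more than a single error number before
trusting machine transcripts for symptom tracking or safety monitoring.
It compares a human reference transcript (diarized into therapist /
patient / unknown utterances, timestamped at each speaker change)
against an ASR hypothesis along three prongs:

1. **Domain-agnostic accuracy.** Word error rate from a minimum-cost
   word alignment, `WER = (S + D + I) / N` — substitutions, deletions
   and insertions over the reference word count. Exact surface match is
   required; homophones (*buy*/*bye*) count as errors. WER is reported
   per utterance, per speaker, per session (pooled counts) and per
   cohort. Because WER weighs all errors equally, a **semantic
   distance** is computed alongside: each sentence's words are embedded
   (word2vec-style table, pluggable), and the earth mover (optimal
   transport) distance between the two sentences' word-frequency
   distributions is solved with Euclidean ground cost — zero means the
   same in-vocabulary words, and calibration anchors (random word pairs,
   random sentence pairs, paraphrases) locate any value on its scale.
   Mean-pooled Euclidean and cosine distances are computed as the
   degenerate pooled-vector alternatives.
2. **Depression-symptom accuracy.** Each of the nine PHQ-9 items defines
   a category of clinical keywords (shipped frozen, overridable from
   YAML). A reference keyword occurrence is a true positive only when
   the alignment matches every token of the span exactly; anything else
   is a false negative, and unfaithful hypothesis keywords are false
   positives. Sensitivity `TP/(TP+FN)` and positive predictive value
   `TP/(TP+FP)` are reported per keyword, per category, and as a
   weighted average over pooled counts.
3. **Harm-related accuracy.** Clinician-annotated harm utterances (a
   TSV of session/utterance indices) are evaluated as a subset and
   compared against the rest with a normality-gated procedure:
   Shapiro–Wilk screening per group, Levene's test recorded, then
   two-tailed Welch's *t* (both groups normal) or Mann–Whitney *U*
   otherwise, significance at α = 0.01.

Because real therapy recordings are private, a **synthetic corpus
generator** produces paired transcripts with realistic session shapes
(therapist ≈ 2909 ± 1128 words, patient ≈ 3665 ± 1550) and a controlled
per-token error channel (substitution/deletion/insertion rates, homophone
confusion table, keyword error multiplier), returning the exact injected
op log as ground truth — so every metric is verifiable end to end.

## Worked example

```python
import cteval as cv

ref = cv.SessionTranscript("demo", "reference", (
    cv.Utterance.create("therapist", "How have you been sleeping this week?", 0.0),
    cv.Utterance.create("patient", "Came back and ate some more.", 6.0),
    cv.Utterance.create("patient", "Tuesday I found out my grandmother had died.", 12.0),
))
hyp = cv.SessionTranscript("demo", "hypothesis", (
    cv.Utterance.create("unknown",
        "how have you been sleeping this week came back and eat some more "
        "tuesday i found out my grandmother is dying"),
))
pair = cv.pair_sessions(ref, hyp)     # global alignment carves the hypothesis
session = cv.session_wer(pair)
print(f"session WER = {session.errors}/{session.N} = {session.wer:.3f}")
for sp in ("therapist", "patient"):
    print(f"{sp} WER = {cv.speaker_wer(pair, sp).wer:.3f}")
```

prints

```
session WER = 3/21 = 0.143
therapist WER = 0.000
patient WER = 0.214
```

The undiarized hypothesis was split back into utterance-sized units by
the global word alignment; the therapist's question survived intact,
while the patient's speech lost one word in five (*ate*→*eat*,
*had died*→*is dying*). Whether those errors matter is what the other
two prongs answer: `examples/02_semantic_distance.py` shows the same
1-substitution WER scoring EMD 0.07 (*died*→*dying*, meaning kept)
versus 1.94 (*died*→*made*, meaning destroyed), and
`examples/03_phq9_keywords.py` shows *depressed*→*the preston* counted
as a missed PHQ-2 keyword. Each script under `examples/` is a short
narrative of one capability; the `cteval` CLI
(`wer | semantic | phq | harm | simulate | report`) exposes the same
pipeline for shell use, e.g.

```bash
cteval simulate --sessions 4 --seed 5 --outdir cohort/
cteval wer --ref 'cohort/reference/*.tsv' --hyp 'cohort/hypothesis/*.tsv'
```

## Data formats

* **Transcripts** — TSV (`speaker<TAB>start<TAB>text`, `MM:SS` or
  seconds, `#`-headers for session id and speaker metadata) or JSON;
  writers for both, UTF-8 throughout.
* **Embeddings** — word2vec text format (`count dim` header) or
  two-column TSV.
* **Lexicon** — YAML (`categories: [{id, label, keywords}]`).
* **Harm annotations** — TSV `session_id<TAB>utterance_index<TAB>speaker`.

See `docs/methods.md` for the models, assumptions, parameter defaults
and known limitations.
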