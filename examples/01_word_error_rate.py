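"""Word error rate on a tiny two-speaker session.

Builds a three-utterance reference transcript and a slightly corrupted
ASR hypothesis, pairs them, and reports WER per speaker and pooled.
"""

import cteval as cv

ref = cv.SessionTranscript(
    "demo",
    "reference",
    (
        cv.Utterance.create("therapist", "How have you been sleeping this week?", 0.0),
        cv.Utterance.create("patient", "Came back and ate some more.", 6.0),
        cv.Utterance.create("patient", "Tuesday I found out my grandmother had died.", 12.0),
    ),
)
hyp = cv.SessionTranscript(
    "demo",
    "hypothesis",
    (
        cv.Utterance.create(
            "unknown",
            "how have you been sleeping this week came back and eat some more "
            "tuesday i found out my grandmother is dying",
        ),
    ),
)

pair = cv.pair_sessions(ref, hyp)  # global alignment carves the hypothesis
for unit, alignment in zip(pair.units, pair.unit_alignments()):
    w = cv.compute_wer(alignment)
    print(f"{unit.speaker.value:9s} ref={' '.join(unit.ref_tokens)!r}")
    print(f"          hyp={' '.join(unit.hyp_tokens)!r}  S={w.S} D={w.D} I={w.I} N={w.N}")

session = cv.session_wer(pair)
print(f"\nsession WER = (S+D+I)/N = {session.errors}/{session.N} = {session.wer:.3f}")
for sp in ("therapist", "patient"):
    print(f"{sp} WER = {cv.speaker_wer(pair, sp).wer:.3f}")
# A WER of ~0.14 means one word in seven differs from the human
# reference; homophones and tense changes (ate -> eat) count as errors.
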