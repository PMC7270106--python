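"""Clinical keyword detection: PHQ-9 sensitivity and PPV.

A keyword is a true positive only when the ASR transcribed it exactly;
"depressed" -> "the preston" is a false negative, and keyword-for-keyword
substitutions count once as FN and once as FP.
"""

import cteval as cv

lex = cv.build_phq9_lexicon()
for cat in lex.categories[:3]:
    print(f"PHQ-{cat.category_id} ({cat.label}): {[' '.join(k) for k in cat.keywords]}")

ref = cv.SessionTranscript(
    "demo",
    "reference",
    (
        cv.Utterance.create("patient", "I have still been feeling depressed", 0.0),
        cv.Utterance.create("patient", "I was tired and restless all week", 5.0),
        cv.Utterance.create("patient", "My grandmother's death hit me hard", 10.0),
    ),
)
hyp = cv.SessionTranscript(
    "demo",
    "hypothesis",
    (
        cv.Utterance.create(
            "unknown",
            "i have still been feeling the preston i was tired and restless "
            "all week my grandmother's dead hit me hard",
        ),
    ),
)
pair = cv.pair_sessions(ref, hyp)
for c in cv.classify_keyword_outcomes(pair, lex):
    if c.TP or c.FN or c.FP:
        print(f"  {c.name!r} (PHQ-{c.category_id}): TP={c.TP} FN={c.FN} FP={c.FP}")

cats = cv.category_confusions(cv.classify_keyword_outcomes(pair, lex), lex)
agg = cv.aggregate_categories(cats)
print(
    f"weighted average over {agg.n_positives} occurrences: "
    f"sensitivity {agg.sensitivity_pct}%  PPV {agg.ppv_pct}%"
)
# "depressed" and "death" were lost (FN); "dead" appeared without a
# faithful counterpart (FP); "tired" and "restless" survived (TP).
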