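"""Semantic distance: errors that change meaning vs errors that do not.

Uses a small hand-set embedding table in which "died" and "dying" are
close while "died" and "made" are far, so the same single-substitution
WER yields very different semantic distances.
"""

import numpy as np

import cteval as cv

table = cv.EmbeddingTable(
    2,
    {
        "grandmother": np.array([4.0, 0.0]),
        "my": np.array([0.2, 0.1]),
        "died": np.array([0.0, 3.0]),
        "dying": np.array([0.2, 2.9]),
        "made": np.array([3.0, -2.0]),
    },
)

ref = "my grandmother died".split()
near = "my grandmother dying".split()  # meaning preserved
far = "my grandmother made".split()  # meaning destroyed

for hyp in (near, far):
    wer = cv.compute_wer(cv.align_words(ref, hyp)).wer
    d = cv.sentence_distance(ref, hyp, table)
    print(
        f"hyp={' '.join(hyp)!r}: WER={wer:.2f}  EMD={d.emd:.2f}  "
        f"cosine={d.cosine:.3f}  pooled-euclidean={d.pooled_euclidean:.2f}"
    )
# Both hypotheses have WER 1/3, but the earth mover distance separates
# the harmless tense error from the hallucination.

corpus = [ref, near, far, ["my", "grandmother"], ["died", "dying"]]
cal = cv.calibration_baselines(table, corpus, [(ref, list(reversed(ref)))], n_samples=50, seed=0)
print(
    f"calibration anchors: random words {cal.random_word_distance:.2f}, "
    f"random sentences {cal.random_sentence_distance:.2f}, "
    f"paraphrases {cal.paraphrase_distance:.2f}"
)
# Distances are only meaningful relative to these anchors for a given
# embedding table: word-order paraphrases sit at 0, random pairs far up.
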