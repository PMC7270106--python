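import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import cteval as cv  # noqa: E402


@pytest.fixture(scope="session")
def lexicon():
    return cv.build_phq9_lexicon()


@pytest.fixture(scope="session")
def tiny_table():
    """Hand-set 2-d embeddings for exactly solvable distance checks."""
    return cv.EmbeddingTable(
        2,
        {
            "a": np.array([1.0, 0.0]),
            "b": np.array([0.0, 1.0]),
            "c": np.array([1.0, 1.0]),
            "u": np.array([0.0, 0.0]),
            "v": np.array([2.0, 4.0]),
            "w": np.array([-1.0, 0.0]),
        },
    )


@pytest.fixture(scope="session")
def identity_pair():
    """A small session paired with itself (perfect transcription)."""
    ref = cv.SessionTranscript(
        "s1",
        "reference",
        (
            cv.Utterance.create("therapist", "Do you have any plans to hurt yourself?", 0.0),
            cv.Utterance.create("patient", "I have still been feeling depressed", 5.0),
            cv.Utterance.create("patient", "Came back and ate some more.", 10.0),
        ),
    )
    hyp = cv.SessionTranscript("s1", "hypothesis", ref.utterances)
    return cv.pair_sessions(ref, hyp)


def make_pair(ref_texts, hyp_texts, speakers=None, session_id="s"):
    """Build a global-aligned pair from parallel utterance text lists."""
    speakers = speakers or ["patient"] * len(ref_texts)
    ref = cv.SessionTranscript(
        session_id,
        "reference",
        tuple(
            cv.Utterance.create(sp, tx, float(5 * i))
            for i, (sp, tx) in enumerate(zip(speakers, ref_texts))
        ),
    )
    hyp = cv.SessionTranscript(
        session_id,
        "hypothesis",
        tuple(cv.Utterance.create("unknown", tx, float(5 * i)) for i, tx in enumerate(hyp_texts)),
    )
    return cv.pair_sessions(ref, hyp)


@pytest.fixture(scope="session")
def small_cohort():
    """Three corrupted sessions at moderate rates, shared across tests."""
    profile = cv.SessionProfile(
        therapist_words=(400, 80), patient_words=(500, 100), keyword_rate=0.02, seed=11
    )
    cfg = cv.CorruptionConfig(sub_rate=0.08, del_rate=0.04, ins_rate=0.04, seed=11)
    return cv.build_paired_cohort(3, profile, cfg)
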