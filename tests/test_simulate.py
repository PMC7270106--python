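"""Synthetic corpus generator and the controlled error channel."""

import numpy as np
import pytest

import cteval as cv
from cteval.errors import ValidationError


def _small_profile(**kw):
    defaults = dict(therapist_words=(300, 60), patient_words=(380, 80), seed=7)
    defaults.update(kw)
    return cv.SessionProfile(**defaults)


def test_reference_session_shape(lexicon):
    t = cv.generate_reference_session(_small_profile(), lexicon)
    assert t.source == "reference"
    assert t.word_count == sum(len(u.tokens) for u in t.utterances)
    speakers = {u.speaker for u in t.utterances}
    assert speakers == {cv.Speaker.THERAPIST, cv.Speaker.PATIENT}
    starts = [u.start_time for u in t.utterances]
    assert starts == sorted(starts)


def test_generation_deterministic(lexicon):
    p = _small_profile(keyword_rate=0.02)
    assert cv.generate_reference_session(p, lexicon) == cv.generate_reference_session(p, lexicon)


def test_zero_keyword_rate_means_no_keywords(lexicon):
    t = cv.generate_reference_session(_small_profile(keyword_rate=0.0), lexicon)
    assert cv.find_keyword_spans(t.tokens(), lexicon) == []


def test_word_totals_match_profile(lexicon):
    # law of large numbers over sessions: empirical per-speaker means
    # approach the profile means
    profile = cv.SessionProfile(seed=100)
    tot_p, tot_t, n = 0, 0, 40
    for i in range(n):
        t = cv.generate_reference_session(
            cv.SessionProfile(seed=100 + i), lexicon
        )
        tot_p += t.speaker_word_count("patient")
        tot_t += t.speaker_word_count("therapist")
    assert tot_p / n == pytest.approx(3665, rel=0.10)
    assert tot_t / n == pytest.approx(2909, rel=0.10)


def test_impossible_profile_rejected():
    with pytest.raises(ValidationError):
        cv.SessionProfile(patient_words=(-5, 1))


def test_no_corruption_is_identity(lexicon):
    ref = cv.generate_reference_session(_small_profile(), lexicon)
    hyp, truth = cv.corrupt_session(ref, cv.CorruptionConfig(0, 0, 0, seed=1), lexicon)
    assert hyp.tokens() == ref.tokens()
    assert truth.injected_ops == ()
    assert truth.injected_error_rate == 0.0


def test_total_deletion(lexicon):
    ref = cv.generate_reference_session(_small_profile(), lexicon)
    hyp, truth = cv.corrupt_session(ref, cv.CorruptionConfig(0.0, 1.0, 0.0, seed=1), lexicon)
    assert hyp.tokens() == []
    assert truth.injected_D == ref.word_count


def test_substitution_rate_concentrates(lexicon):
    profile = cv.SessionProfile(
        therapist_words=(5000, 1), patient_words=(5000, 1), keyword_rate=0.0, seed=3
    )
    ref = cv.generate_reference_session(profile, lexicon)
    hyp, truth = cv.corrupt_session(ref, cv.CorruptionConfig(0.1, 0.0, 0.0, seed=3), lexicon)
    assert truth.injected_S / truth.n_ref_tokens == pytest.approx(0.1, abs=0.01)
    assert truth.injected_D == truth.injected_I == 0


def test_ground_truth_tallies_match_ops(small_cohort):
    for _, truth in small_cohort:
        kinds = [o.kind for o in truth.injected_ops]
        assert truth.injected_S == kinds.count("substitution")
        assert truth.injected_D == kinds.count("deletion")
        assert truth.injected_I == kinds.count("insertion")


def test_measured_wer_bounded_by_injected(small_cohort):
    # the DP can only find a script at most as expensive as the injected one
    for pair, truth in small_cohort:
        measured = cv.session_wer(pair)
        assert measured.errors <= truth.injected_S + truth.injected_D + truth.injected_I


def test_expected_error_rate():
    assert cv.expected_error_rate(cv.CorruptionConfig(0.1, 0.05, 0.05)) == pytest.approx(0.2)
    assert cv.expected_error_rate(cv.CorruptionConfig(0, 0, 0)) == 0.0
    assert cv.expected_error_rate(cv.CorruptionConfig(0.5, 0.5, 0.0)) == pytest.approx(1.0)


def test_invalid_rates_rejected():
    with pytest.raises(ValidationError):
        cv.CorruptionConfig(sub_rate=0.7, del_rate=0.5)
    with pytest.raises(ValidationError):
        cv.CorruptionConfig(sub_rate=-0.1)


def test_confusion_table_substitutions(lexicon):
    ref = cv.SessionTranscript(
        "s", "reference", (cv.Utterance.create("p", "buy buy buy buy buy", 0.0),)
    )
    cfg = cv.CorruptionConfig(
        sub_rate=1.0, del_rate=0.0, ins_rate=0.0,
        confusion_table=cv.default_confusion_table(), seed=5,
    )
    hyp, truth = cv.corrupt_session(ref, cfg, lexicon)
    assert truth.injected_S == 5
    assert set(hyp.tokens()) <= {"bye", "by"}  # homophones only


def test_keyword_multiplier_raises_keyword_errors(lexicon):
    # keyword tokens err at min(1, m*s); with m*s >= 1 every keyword breaks
    profile = _small_profile(keyword_rate=0.05, seed=21)
    ref = cv.generate_reference_session(profile, lexicon)
    cfg = cv.CorruptionConfig(0.1, 0.0, 0.0, keyword_error_multiplier=10.0, seed=21)
    hyp, truth = cv.corrupt_session(ref, cfg, lexicon)
    assert truth.keyword_outcomes  # keywords were injected
    assert all(not k.transcribed for k in truth.keyword_outcomes)


def test_cohort_reproducible_and_distinct(lexicon):
    profile = _small_profile()
    cfg = cv.CorruptionConfig(0.05, 0.02, 0.02, seed=7)
    c1 = cv.build_paired_cohort(3, profile, cfg, lexicon)
    c2 = cv.build_paired_cohort(3, profile, cfg, lexicon)
    for (p1, t1), (p2, t2) in zip(c1, c2):
        assert p1.reference == p2.reference
        assert p1.hypothesis == p2.hypothesis
        assert t1 == t2
    # different sessions are not identical
    assert c1[0][0].reference.tokens() != c1[1][0].reference.tokens()


def test_ground_truth_agrees_with_classifier(small_cohort, lexicon):
    """The alignment-based keyword classifier recovers the injected
    keyword outcomes except for rare alignment ambiguities."""
    agree = total = 0
    for pair, truth in small_cohort:
        confusions = cv.classify_keyword_outcomes(pair, lexicon)
        measured_tp = sum(c.TP for c in confusions)
        true_tp = sum(1 for k in truth.keyword_outcomes if k.transcribed)
        total += len(truth.keyword_outcomes)
        agree += len(truth.keyword_outcomes) - abs(measured_tp - true_tp)
    assert total > 0
    assert agree / total >= 0.99


def test_write_cohort_roundtrip(tmp_path, small_cohort):
    cv.write_cohort(small_cohort[:1], tmp_path)
    pair, truth = small_cohort[0]
    sid = pair.session_id
    ref = cv.parse_transcript(tmp_path / "reference" / f"{sid}.tsv")
    hyp = cv.parse_transcript(tmp_path / "hypothesis" / f"{sid}.tsv")
    assert ref == pair.reference
    assert hyp == pair.hypothesis
    assert (tmp_path / "truth" / f"{sid}.json").exists()
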