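"""Embedding table, pooling, and the semantic distance family."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

import cteval as cv
from cteval.errors import UndefinedMetricError, ValidationError
from oracles import brute_force_emd


def test_mean_pooling(tiny_table):
    assert np.allclose(cv.mean_pool_embedding(["v"], tiny_table), [2, 4])
    assert np.allclose(cv.mean_pool_embedding(["u", "v"], tiny_table), [1, 2])
    # drop policy: OOV tokens simply vanish from the mean
    assert np.allclose(cv.mean_pool_embedding(["u", "zzz"], tiny_table), [0, 0])
    with pytest.raises(UndefinedMetricError):
        cv.mean_pool_embedding(["zzz"], tiny_table)


def test_zero_policy_changes_denominator(tiny_table):
    zt = cv.EmbeddingTable(2, dict(tiny_table.vectors), oov_policy="zero")
    assert np.allclose(cv.mean_pool_embedding(["v", "zzz"], zt), [1, 2])


def test_emd_basic(tiny_table):
    assert cv.emd_distance("a b c".split(), "a b c".split(), tiny_table) == 0.0
    assert cv.emd_distance(["u"], ["v"], tiny_table) == pytest.approx(np.hypot(2, 4))
    # ref={a,b} half mass each, hyp={c}: both unit moves cost 1
    assert cv.emd_distance(["a", "b"], ["c"], tiny_table) == pytest.approx(1.0)
    with pytest.raises(UndefinedMetricError):
        cv.emd_distance(["zzz"], ["a"], tiny_table)


def test_cosine_endpoints(tiny_table):
    assert cv.cosine_distance(["a"], ["a"], tiny_table) == 0.0
    assert cv.cosine_distance(["a"], ["b"], tiny_table) == pytest.approx(1.0)
    assert cv.cosine_distance(["a"], ["w"], tiny_table) == pytest.approx(2.0)
    with pytest.raises(UndefinedMetricError):
        cv.cosine_distance(["u"], ["a"], tiny_table)  # zero-norm pooled vector


def test_single_word_emd_equals_pooled_euclidean(tiny_table):
    for x in "abc":
        for y in "uvw":
            assert cv.emd_distance([x], [y], tiny_table) == pytest.approx(
                cv.pooled_euclidean_distance([x], [y], tiny_table)
            )


@settings(max_examples=40, deadline=None)
@given(st.data())
def test_emd_matches_brute_force_transport(data):
    words = [f"q{i}" for i in range(8)]
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    table = cv.random_embedding_table(words, dimension=5, seed=int(rng.integers(2**31)))
    ref = data.draw(st.lists(st.sampled_from(words), min_size=1, max_size=4))
    hyp = data.draw(st.lists(st.sampled_from(words), min_size=1, max_size=4))
    got = cv.emd_distance(ref, hyp, table)
    ru, rc = np.unique(ref, return_counts=True)
    hu, hc = np.unique(hyp, return_counts=True)
    C = cdist(np.stack([table[w] for w in ru]), np.stack([table[w] for w in hu]))
    expected = brute_force_emd(rc / rc.sum(), hc / hc.sum(), C)
    assert got == pytest.approx(expected, abs=1e-6)


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_emd_metric_properties(data):
    words = [f"q{i}" for i in range(6)]
    table = cv.random_embedding_table(words, dimension=4, seed=3)
    sents = [
        data.draw(st.lists(st.sampled_from(words), min_size=1, max_size=3)) for _ in range(3)
    ]
    a, b, c = sents
    dab = cv.emd_distance(a, b, table)
    dba = cv.emd_distance(b, a, table)
    dac = cv.emd_distance(a, c, table)
    dcb = cv.emd_distance(c, b, table)
    assert dab == pytest.approx(dba, abs=1e-9)  # symmetry
    assert dab <= dac + dcb + 1e-9  # triangle inequality
    assert cv.emd_distance(a, a, table) == 0.0  # identity


def test_scaling_behaviour(tiny_table):
    scaled = cv.EmbeddingTable(2, {w: 3.0 * v for w, v in tiny_table.vectors.items()})
    ref, hyp = ["a", "b"], ["c", "v"]
    assert cv.emd_distance(ref, hyp, scaled) == pytest.approx(
        3.0 * cv.emd_distance(ref, hyp, tiny_table)
    )
    assert cv.pooled_euclidean_distance(ref, hyp, scaled) == pytest.approx(
        3.0 * cv.pooled_euclidean_distance(ref, hyp, tiny_table)
    )
    assert cv.cosine_distance(ref, hyp, scaled) == pytest.approx(
        cv.cosine_distance(ref, hyp, tiny_table)
    )  # cosine is scale-invariant


def test_frequency_vs_uniform_weights(tiny_table):
    # repeated words shift mass under frequency weighting
    ref, hyp = ["a", "a", "b"], ["c"]
    freq = cv.emd_distance(ref, hyp, tiny_table)
    uni = cv.emd_distance(ref, hyp, tiny_table, uniform_weights=True)
    assert freq == pytest.approx(1.0)  # all moves to c cost 1 here
    assert uni == pytest.approx(1.0)
    ref2, hyp2 = ["u", "u", "v"], ["u"]
    assert cv.emd_distance(ref2, hyp2, tiny_table) == pytest.approx(np.hypot(2, 4) / 3)
    assert cv.emd_distance(ref2, hyp2, tiny_table, uniform_weights=True) == pytest.approx(
        np.hypot(2, 4) / 2
    )


def test_session_distance_excludes_unembeddable_units(tiny_table):
    from conftest import make_pair

    pair = make_pair(["a b", "zzz yyy", "u"], ["a b", "zzz yyy", "v"])
    res = cv.session_semantic_distance(pair, tiny_table)
    assert res.n_excluded == 1
    assert res.summary.n == 2
    assert res.summary.mean == pytest.approx((0.0 + np.hypot(2, 4)) / 2)


def test_sentence_distance_bundle(tiny_table):
    d = cv.sentence_distance(["a", "b"], ["c"], tiny_table)
    assert d.emd == pytest.approx(1.0)
    assert d.n_ref_tokens_used == 2 and d.n_hyp_tokens_used == 1


def test_word2vec_text_roundtrip(tmp_path, tiny_table):
    path = tmp_path / "emb.txt"
    tiny_table.save_word2vec_text(path)
    loaded = cv.EmbeddingTable.load_word2vec_text(path)
    assert loaded.dimension == 2
    for w, v in tiny_table.vectors.items():
        assert np.array_equal(loaded[w], v)
    with pytest.raises(ValidationError):
        cv.EmbeddingTable.load_word2vec_text(io.StringIO("no header here\n"))


def test_embedding_tsv_reader(tmp_path):
    p = tmp_path / "emb.tsv"
    p.write_text("alpha\t1 0\nbeta\t0 1\n")
    t = cv.EmbeddingTable.load_tsv(p)
    assert t.dimension == 2 and "beta" in t


def test_calibration_baselines_deterministic(tiny_table):
    corpus = [["a", "b"], ["c"], ["u", "v"], ["a", "c", "b"]]
    paras = [(["a", "b"], ["b", "a"])]
    r1 = cv.calibration_baselines(tiny_table, corpus, paras, n_samples=30, seed=9)
    r2 = cv.calibration_baselines(tiny_table, corpus, paras, n_samples=30, seed=9)
    assert r1 == r2
    assert r1.paraphrase_distance == pytest.approx(0.0)  # word-order paraphrase
    assert r1.random_word_distance > 0
    none = cv.calibration_baselines(tiny_table, corpus, (), n_samples=5, seed=1)
    assert none.paraphrase_distance is None


def test_calibration_degenerate_inputs():
    one = cv.random_embedding_table(["solo"], dimension=3, seed=0)
    r = cv.calibration_baselines(one, [["solo"], ["solo"]], n_samples=5, seed=0)
    assert r.random_word_distance == 0.0  # single-word vocabulary
    assert r.random_sentence_distance == 0.0  # identical sentences
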