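"""End-to-end report generation and the command-line interface."""

import json
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner

import cteval as cv
from cteval.cli import main as cli_main
from cteval.errors import ConfigError


@pytest.fixture(scope="module")
def identity_cohort_dir(tmp_path_factory):
    """A 4-session cohort written to disk with hypothesis == reference."""
    root = tmp_path_factory.mktemp("identity")
    profile = cv.SessionProfile(
        therapist_words=(200, 30), patient_words=(250, 40), keyword_rate=0.02, seed=3
    )
    cohort = cv.build_paired_cohort(
        4, profile, cv.CorruptionConfig(0, 0, 0, seed=3)
    )
    cv.write_cohort(cohort, root)
    vocab = sorted({t for p, _ in cohort for t in p.reference.tokens()})
    table = cv.random_embedding_table(vocab, dimension=8, seed=3)
    table.save_word2vec_text(root / "embeddings.txt")
    return root


def _config(root, outdir, **kw):
    cfg = cv.EvaluationConfig(
        reference_glob=str(root / "reference" / "*.tsv"),
        hypothesis_glob=str(root / "hypothesis" / "*.tsv"),
        embeddings_path=str(root / "embeddings.txt"),
        output_dir=str(outdir),
        **kw,
    )
    return cfg


def test_identity_cohort_report(identity_cohort_dir, tmp_path):
    bundle = cv.run_evaluation(_config(identity_cohort_dir, tmp_path / "out"))
    dom = bundle["domain_agnostic"]
    agg = dom[dom.group == "aggregate"].iloc[0]
    assert agg.error_rate_pct == 0
    assert float(agg.semantic_distance) == 0.0
    phq = bundle["phq9_keywords"]
    w = phq[phq.category == "weighted average"].iloc[0]
    assert w.sensitivity_pct == 100 and w.ppv_pct == 100
    assert bundle["harm_subset"] is None  # no annotations configured
    log = json.loads(Path(bundle["paths"]["run_log"]).read_text())
    assert log["n_sessions"] == 4


def test_report_is_byte_deterministic(identity_cohort_dir, tmp_path):
    b1 = cv.run_evaluation(_config(identity_cohort_dir, tmp_path / "o1"))
    b2 = cv.run_evaluation(_config(identity_cohort_dir, tmp_path / "o2"))
    for key in ("domain_agnostic", "phq9_keywords"):
        f1 = Path(b1["paths"][key]).read_bytes()
        f2 = Path(b2["paths"][key]).read_bytes()
        assert f1 == f2


def test_missing_embeddings_is_config_error(identity_cohort_dir, tmp_path):
    cfg = _config(identity_cohort_dir, tmp_path / "out")
    cfg.embeddings_path = None
    with pytest.raises(ConfigError):
        cv.run_evaluation(cfg)
    # but semantic=False runs without a table
    cfg.semantic = False
    bundle = cv.run_evaluation(cfg)
    assert "semantic_distance" not in bundle["domain_agnostic"].columns


def test_corrupted_cohort_error_rate_near_injected(tmp_path):
    profile = cv.SessionProfile(
        therapist_words=(700, 50), patient_words=(900, 60), keyword_rate=0.0, seed=9
    )
    cohort = cv.build_paired_cohort(4, profile, cv.CorruptionConfig(0.1, 0.05, 0.05, seed=9))
    cfg = cv.EvaluationConfig(output_dir=str(tmp_path / "out"), semantic=False)
    bundle = cv.run_evaluation(cfg, pairs=[p for p, _ in cohort])
    agg = bundle["domain_agnostic"].iloc[0]
    assert 15 <= agg.error_rate_pct <= 20  # at or just under the 20% injected


def test_yaml_config_loading(tmp_path, identity_cohort_dir):
    cfg_path = tmp_path / "cfg.yaml"
    cfg_path.write_text(
        "reference_glob: '{}'\nhypothesis_glob: '{}'\nsemantic: false\n"
        "output_dir: '{}'\nnormalization: {{keep_fillers: false}}\n".format(
            identity_cohort_dir / "reference" / "*.tsv",
            identity_cohort_dir / "hypothesis" / "*.tsv",
            tmp_path / "out",
        )
    )
    cfg = cv.load_config(cfg_path)
    assert cfg.normalization.keep_fillers is False
    with pytest.raises(ConfigError):
        bad = tmp_path / "bad.yaml"
        bad.write_text("not_a_key: 1\n")
        cv.load_config(bad)


def test_report_with_harm_annotations(identity_cohort_dir, tmp_path):
    refs = sorted((identity_cohort_dir / "reference").glob("*.tsv"))
    sid = cv.parse_transcript(refs[0]).session_id
    ann_path = tmp_path / "harm.tsv"
    ann_path.write_text(f"{sid}\t0\ttherapist\n{sid}\t1\tpatient\n{sid}\t2\ttherapist\n")
    cfg = _config(identity_cohort_dir, tmp_path / "out", annotations_path=str(ann_path))
    bundle = cv.run_evaluation(cfg)
    harm = bundle["harm_subset"]
    assert harm is not None
    row = harm[harm.group == "harm_subset"].iloc[0]
    assert row.n_units == 3
    assert row.wer_mean_pct == 0  # identity cohort: perfect transcription
    cmp_rows = harm[harm.group == "comparison:wer"]
    assert len(cmp_rows) == 1
    assert cmp_rows.iloc[0].significant == False  # noqa: E712 - pandas bool


def test_cli_wer_and_phq(identity_cohort_dir, tmp_path):
    runner = CliRunner()
    ref = str(identity_cohort_dir / "reference" / "*.tsv")
    hyp = str(identity_cohort_dir / "hypothesis" / "*.tsv")
    res = runner.invoke(cli_main, ["wer", "--ref", ref, "--hyp", hyp])
    assert res.exit_code == 0, res.output
    df = pd.read_csv(pd.io.common.StringIO(res.output))
    assert (df.wer == 0).all()
    res = runner.invoke(cli_main, ["phq", "--ref", ref, "--hyp", hyp])
    assert res.exit_code == 0
    assert "weighted average" in res.output


def test_cli_simulate_then_report(tmp_path):
    runner = CliRunner()
    outdir = tmp_path / "cohort"
    res = runner.invoke(
        cli_main,
        ["simulate", "--sessions", "2", "--seed", "5", "--outdir", str(outdir),
         "--keyword-rate", "0.01"],
    )
    assert res.exit_code == 0, res.output
    assert len(list((outdir / "reference").glob("*.tsv"))) == 2
    res = runner.invoke(
        cli_main,
        ["wer", "--ref", str(outdir / "reference" / "*.tsv"),
         "--hyp", str(outdir / "hypothesis" / "*.tsv"),
         "--out", str(tmp_path / "wer.csv")],
    )
    assert res.exit_code == 0, res.output
    df = pd.read_csv(tmp_path / "wer.csv")
    assert set(df.columns) == {"session_id", "speaker", "S", "D", "I", "N", "wer"}
    assert (df.wer > 0).any()


def test_cli_validation_exit_code(tmp_path):
    runner = CliRunner()
    res = runner.invoke(
        cli_main, ["wer", "--ref", str(tmp_path / "none*.tsv"), "--hyp", str(tmp_path / "x*.tsv")]
    )
    assert res.exit_code == 1  # validation error: no resolvable pairs
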