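"""Orchestration: run the full three-pronged evaluation and write CSVs.

``run_evaluation`` resolves a cohort of reference/hypothesis transcript
pairs, computes per-session WER and semantic distance, the PHQ-9 keyword
confusion table, and (when annotations are supplied) the harm-subset
report with its comparison against the remaining units, then writes:

* ``domain_agnostic.csv`` — aggregate / per-speaker / per-gender rows
  with error-rate and semantic-distance mean ± SD and Shapiro–Wilk
  normality p-values;
* ``phq9_keywords.csv`` — per-category and weighted-average keyword
  sensitivity/PPV rows;
* ``harm_subset.csv`` — subset summaries and subset-vs-rest comparisons
  (only when annotations are given);
* ``run_log.json`` — configuration, seeds and software versions.

Percentages are printed at integer precision and distances at two
decimals; re-running with the same inputs produces byte-identical files.
"""

from __future__ import annotations

import glob as globmod
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, EmptyGroupError, UndefinedMetricError
from .lexicon import (
    KeywordLexicon,
    aggregate_categories,
    build_phq9_lexicon,
    category_confusions,
    classify_keyword_outcomes,
    load_lexicon,
)
from .semantic import EmbeddingTable, emd_distance, session_semantic_distance
from .stats import compare_groups, load_annotations, normality_gate, select_harm_subset, subset_report
from .transcripts import (
    NormalizationConfig,
    SessionPair,
    Speaker,
    parse_transcript,
    pair_sessions,
)
from .wer import compute_wer, session_wer, speaker_wer, summarize_metric

__all__ = ["EvaluationConfig", "run_evaluation", "load_config", "resolve_pairs"]


@dataclass
class EvaluationConfig:
    reference_glob: str = ""
    hypothesis_glob: str = ""
    pairing_mode: str = "global_align"
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    embeddings_path: Optional[str] = None
    lexicon_path: Optional[str] = None
    annotations_path: Optional[str] = None
    output_dir: str = "cteval-report"
    alpha: float = 0.01
    semantic: bool = True  # compute semantic metrics (needs embeddings)


def load_config(path: str | Path) -> EvaluationConfig:
    """Read an :class:`EvaluationConfig` from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    norm = NormalizationConfig(**doc.pop("normalization", {}))
    known = {f for f in EvaluationConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return EvaluationConfig(normalization=norm, **doc)


def resolve_pairs(cfg: EvaluationConfig) -> list[SessionPair]:
    """Match reference and hypothesis transcript files by session id."""
    refs = {}
    for p in sorted(globmod.glob(cfg.reference_glob)):
        t = parse_transcript(p, cfg=cfg.normalization, default_source="reference")
        refs[t.session_id] = t
    pairs = []
    for p in sorted(globmod.glob(cfg.hypothesis_glob)):
        h = parse_transcript(p, cfg=cfg.normalization, default_source="hypothesis")
        if h.session_id in refs:
            pairs.append(pair_sessions(refs[h.session_id], h, mode=cfg.pairing_mode))
    if not pairs:
        raise ConfigError(
            f"no session pairs resolvable from {cfg.reference_glob!r} / {cfg.hypothesis_glob!r}"
        )
    return pairs


def _shapiro_p(values) -> Optional[float]:
    if len(values) < 3:
        return None
    return normality_gate(values).p_value


def _fmt_p(p: Optional[float]) -> str:
    if p is None:
        return ""
    return "<0.001" if p < 0.001 else f"{p:.2f}"


def _group_row(group: str, wers, dists) -> dict:
    row = {"group": group, "n": len(wers)}
    if wers:
        s = summarize_metric(wers)
        row.update(
            error_rate_pct=int(np.floor(100 * s.mean + 0.5)),
            error_rate_sd_pct=int(np.floor(100 * s.sd + 0.5)),
            error_rate_shapiro_p=_fmt_p(_shapiro_p(wers)),
        )
    if dists:
        s = summarize_metric(dists)
        row.update(
            semantic_distance=f"{s.mean:.2f}",
            semantic_distance_sd=f"{s.sd:.2f}",
            semantic_shapiro_p=_fmt_p(_shapiro_p(dists)),
        )
    return row


def run_evaluation(cfg: EvaluationConfig, pairs: Optional[Sequence[SessionPair]] = None) -> dict:
    """Run all three evaluation prongs and write the report bundle.

    Returns a dict with the output paths and the in-memory DataFrames.
    ``pairs`` may be supplied directly (e.g. from the simulator) to skip
    file resolution.
    """
    if pairs is None:
        pairs = resolve_pairs(cfg)
    pairs = list(pairs)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    table: Optional[EmbeddingTable] = None
    if cfg.semantic:
        if not cfg.embeddings_path:
            raise ConfigError("semantic metrics requested but no embeddings_path configured")
        table = EmbeddingTable.load_word2vec_text(cfg.embeddings_path)
    lex: KeywordLexicon = (
        load_lexicon(cfg.lexicon_path) if cfg.lexicon_path else build_phq9_lexicon()
    )

    # ---- prong 1: domain-agnostic (per-session WER / semantic distance)
    session_wers = [session_wer(p).wer for p in pairs]
    speaker_wers = {sp: [] for sp in (Speaker.PATIENT, Speaker.THERAPIST)}
    for p in pairs:
        for sp in speaker_wers:
            try:
                speaker_wers[sp].append(speaker_wer(p, sp).wer)
            except EmptyGroupError:
                pass
    gender_wers: dict[str, list[float]] = {}
    gender_dists: dict[str, list[float]] = {}
    session_dists: list[float] = []
    speaker_dists = {sp: [] for sp in (Speaker.PATIENT, Speaker.THERAPIST)}
    for idx, p in enumerate(pairs):
        dist_val = None
        if table is not None:
            try:
                dist_val = session_semantic_distance(p, table).summary.mean
                session_dists.append(dist_val)
            except UndefinedMetricError:
                pass
            for sp in speaker_dists:
                vals = []
                for u, a in zip(p.units, p.unit_alignments()):
                    if u.speaker is sp:
                        try:
                            vals.append(emd_distance(u.ref_tokens, u.hyp_tokens, table))
                        except UndefinedMetricError:
                            pass
                if vals:
                    speaker_dists[sp].append(float(np.mean(vals)))
        info = p.reference.speaker_metadata.get(Speaker.PATIENT.value)
        if info is not None and info.gender:
            gender_wers.setdefault(info.gender, []).append(session_wers[idx])
            if dist_val is not None:
                gender_dists.setdefault(info.gender, []).append(dist_val)
    rows = [_group_row("aggregate", session_wers, session_dists)]
    for sp in (Speaker.PATIENT, Speaker.THERAPIST):
        rows.append(_group_row(f"speaker:{sp.value}", speaker_wers[sp], speaker_dists[sp]))
    for g in sorted(gender_wers):
        rows.append(_group_row(f"patient_gender:{g}", gender_wers[g], gender_dists.get(g, [])))
    domain_df = pd.DataFrame(rows)
    domain_path = outdir / "domain_agnostic.csv"
    domain_df.to_csv(domain_path, index=False)

    # ---- prong 2: PHQ-9 keyword confusion table
    kw = classify_keyword_outcomes(pairs, lex)
    cats = category_confusions(kw, lex)
    weighted = aggregate_categories(cats)
    phq_rows = []
    for c in cats + [weighted]:
        phq_rows.append(
            {
                "category": c.category_id if c.category_id is not None else "weighted average",
                "label": c.name,
                "keywords": ", ".join(
                    " ".join(k) for k, cid in lex.all_keywords() if cid == c.category_id
                )
                if c.category_id is not None
                else "",
                "n_positives": c.n_positives,
                "TP": c.TP,
                "FN": c.FN,
                "FP": c.FP,
                "sensitivity_pct": c.sensitivity_pct,
                "ppv_pct": c.ppv_pct,
            }
        )
    phq_df = pd.DataFrame(phq_rows)
    phq_path = outdir / "phq9_keywords.csv"
    phq_df.to_csv(phq_path, index=False)

    # ---- prong 3: harm subset (optional)
    harm_path = None
    harm_df = None
    if cfg.annotations_path:
        annotations = load_annotations(cfg.annotations_path)
        subset = select_harm_subset(pairs, annotations)
        rep = subset_report(subset, table)
        harm_rows = [
            {
                "group": "harm_subset",
                "n_units": rep.n_units,
                "wer_mean_pct": int(np.floor(100 * rep.wer.mean + 0.5)),
                "wer_sd_pct": int(np.floor(100 * rep.wer.sd + 0.5)),
                "semantic_mean": f"{rep.semantic.mean:.2f}" if rep.semantic else "",
            }
        ]
        for sp, vals in sorted(rep.by_speaker.items()):
            harm_rows.append(
                {
                    "group": f"harm_subset:{sp}",
                    "n_units": vals["wer"].n,
                    "wer_mean_pct": int(np.floor(100 * vals["wer"].mean + 0.5)),
                    "wer_sd_pct": int(np.floor(100 * vals["wer"].sd + 0.5)),
                    "semantic_mean": f"{vals['semantic'].mean:.2f}" if vals["semantic"] else "",
                }
            )
        # compare the subset against all remaining units
        marked = {(hu.session_id, hu.unit.ref_indices) for hu in subset}
        rest_wers = []
        rest_dists = []
        for p in pairs:
            for u, a in zip(p.units, p.unit_alignments()):
                if (p.session_id, u.ref_indices) in marked or a.N == 0:
                    continue
                rest_wers.append(compute_wer(a).wer)
                if table is not None:
                    try:
                        rest_dists.append(emd_distance(u.ref_tokens, u.hyp_tokens, table))
                    except UndefinedMetricError:
                        pass
        subset_wers = [
            compute_wer_safe(hu.unit.ref_tokens, hu.unit.hyp_tokens) for hu in subset
        ]
        if len(subset_wers) >= 3 and len(rest_wers) >= 3:
            cmp_wer = compare_groups(
                subset_wers, rest_wers, alpha=cfg.alpha, labels=("harm", "rest")
            )
            harm_rows.append(
                {
                    "group": "comparison:wer",
                    "n_units": cmp_wer.n_a + cmp_wer.n_b,
                    "wer_mean_pct": "",
                    "wer_sd_pct": "",
                    "semantic_mean": "",
                    "test": cmp_wer.chosen_test,
                    "p_value": f"{cmp_wer.p_value:.3g}",
                    "significant": cmp_wer.significant,
                }
            )
        harm_df = pd.DataFrame(harm_rows)
        harm_path = outdir / "harm_subset.csv"
        harm_df.to_csv(harm_path, index=False)

    log = {
        "cteval_version": __version__,
        "python_version": platform.python_version(),
        "n_sessions": len(pairs),
        "pairing_mode": cfg.pairing_mode,
        "alpha": cfg.alpha,
        "embeddings": cfg.embeddings_path,
        "lexicon": cfg.lexicon_path or "builtin phq9",
        "annotations": cfg.annotations_path,
    }
    log_path = outdir / "run_log.json"
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)

    return {
        "domain_agnostic": domain_df,
        "phq9_keywords": phq_df,
        "harm_subset": harm_df,
        "paths": {
            "domain_agnostic": str(domain_path),
            "phq9_keywords": str(phq_path),
            "harm_subset": str(harm_path) if harm_path else None,
            "run_log": str(log_path),
        },
    }


def compute_wer_safe(ref_tokens, hyp_tokens) -> float:
    from .alignment import align_words

    return compute_wer(align_words(ref_tokens, hyp_tokens)).wer
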