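"""End-to-end pipeline: simulate -> preprocess -> extract -> analyse.

Two entry points: ``run_cohort`` keeps everything in memory (one subject at a
time) and returns the cohort GCSR table plus metadata, which is what the
statistics and the examples consume; ``run_pipeline`` is the disk-based
variant behind the CLI, writing EDF/CSV/TSV/JSON artifacts with per-stage
logging and skip-if-present resumability.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .preprocess import preprocess_recording
from .spectral import GcsrSpectrum, cohort_table, subject_gcsr, write_gcsr_tsv
from .stats import format_anova_table, run_study_analyses
from .synth import (EegRecording, SubjectSpec, anxiety_design, default_design,
                    generate_cohort, iter_cohort)
from .task import TrialRecord, classify_trials, read_trial_log

logger = logging.getLogger("gcsr")

__all__ = ["extract_subject", "run_cohort", "run_pipeline", "design_from_config"]


def extract_subject(
    rec: EegRecording,
    trials: Sequence[TrialRecord],
    subject_id: str,
    cfg: PipelineConfig | None = None,
) -> tuple[GcsrSpectrum, dict]:
    """Preprocess one recording and extract its GCSR spectrum."""
    cfg = cfg or PipelineConfig()
    pairs, _, _ = classify_trials(trials)
    epochs, report = preprocess_recording(
        rec, pairs, subject_id=subject_id,
        low_hz=cfg.preprocess.low_hz, high_hz=cfg.preprocess.high_hz,
        target_hz=cfg.preprocess.target_hz,
        blink_threshold_uV=cfg.preprocess.blink_threshold_uV,
        peak_to_peak_uV=cfg.preprocess.peak_to_peak_uV,
        centring=cfg.preprocess.centring,
        reject_channel=cfg.spectral.channel,
    )
    spectrum = subject_gcsr(
        epochs, subject_id,
        channel=cfg.spectral.channel, blocks=cfg.spectral.blocks,
        smooth=cfg.spectral.smooth, log_domain=cfg.spectral.log_domain,
    )
    return spectrum, report


def design_from_config(cfg: PipelineConfig) -> list[SubjectSpec]:
    builder = default_design if cfg.synth.design == "default" else anxiety_design
    return builder(
        boost_uv=cfg.synth.boost_uv,
        null_group=cfg.synth.null_group,
        seed=cfg.seed,
        centre_freq_hz=cfg.synth.centre_freq_hz,
        bandwidth_hz=cfg.synth.bandwidth_hz,
        background_scale_uV=cfg.synth.background_scale_uV,
        background_exponent=cfg.synth.background_exponent,
        blink_rate_hz=cfg.synth.blink_rate_hz,
        blink_amplitude_uV=cfg.synth.blink_amplitude_uV,
    )


def run_cohort(
    design: Sequence[SubjectSpec],
    seed: int,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Simulate and fully process a cohort in memory.

    Returns (wide GCSR table indexed by subject, metadata table, per-subject
    preprocessing reports).
    """
    cfg = cfg or PipelineConfig()
    spectra, meta_rows, reports = [], [], []
    for sub in iter_cohort(design, seed, session_config=cfg.task):
        spectrum, report = extract_subject(sub.recording, sub.trials,
                                           sub.spec.subject_id, cfg)
        spectra.append(spectrum)
        meta_rows.append({"subject_id": sub.spec.subject_id,
                          "group": sub.spec.group,
                          **sub.spec.demographics})
        report["subject_id"] = sub.spec.subject_id
        reports.append(report)
        logger.info("processed %s: %d epochs retained",
                    sub.spec.subject_id, report["n_retained"])
    return cohort_table(spectra), pd.DataFrame(meta_rows), reports


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> Path:
    """Disk-based pipeline run; returns the output directory.

    Stages: simulate cohort (EDF + trial CSV + manifest) -> per-subject GCSR
    extraction (TSV) -> study analyses (JSON + text table).  A stage whose
    outputs already exist is skipped unless ``force``.
    """
    from .config import dump_config
    from .edf import read_edf

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "config_used.yaml")

    raw_dir = out / "raw"
    manifest_path = raw_dir / "manifest.csv"
    if force or not manifest_path.exists():
        logger.info("stage simulate: generating cohort into %s", raw_dir)
        design = design_from_config(cfg)
        generate_cohort(design, cfg.seed, raw_dir, session_config=cfg.task)
    else:
        logger.info("stage simulate: cached (%s)", manifest_path)
    manifest = pd.read_csv(manifest_path)

    gcsr_tsv = out / "gcsr.tsv"
    wide_tsv = out / "gcsr_wide.tsv"
    if force or not wide_tsv.exists():
        logger.info("stage extract: %d subjects", len(manifest))
        spectra, reports = [], []
        for _, row in manifest.iterrows():
            rec = read_edf(raw_dir / row["edf"])
            trials = read_trial_log(raw_dir / row["trials"])
            spectrum, report = extract_subject(rec, trials, row["subject_id"], cfg)
            spectra.append(spectrum)
            report["subject_id"] = row["subject_id"]
            reports.append(report)
        write_gcsr_tsv(spectra, gcsr_tsv)
        cohort_table(spectra).to_csv(wide_tsv, sep="\t")
        (out / "preprocess_report.json").write_text(json.dumps(reports, indent=2))
    else:
        logger.info("stage extract: cached (%s)", wide_tsv)

    results_json = out / "results.json"
    if force or not results_json.exists():
        logger.info("stage analyze")
        wide = pd.read_csv(wide_tsv, sep="\t", index_col="subject_id")
        metadata = manifest[["subject_id", "group"]]
        report = run_study_analyses(wide, metadata)
        report["seed"] = cfg.seed
        results_json.write_text(json.dumps(report, indent=2))
        (out / "anova_table.txt").write_text(format_anova_table(report))
    else:
        logger.info("stage analyze: cached (%s)", results_json)
    return out
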