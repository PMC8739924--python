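"""Stage orchestration: simulate -> extract -> mse -> stats -> classify.

Each stage reads the artifacts of the previous stage from the configured
output directory and writes its own, embedding a provenance block (config
hash, seed, package version) so every output names its inputs. Stages are
idempotent: identical inputs and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import compare_models
from .cohort_stats import compare_groups, comparison_frame
from .config import PipelineConfig, config_hash
from .exceptions import DetectionError, PipelineError
from .fiducial import (
    TD_FEATURE_NAMES,
    aggregate_recording,
    compute_features,
    detect_fiducials,
)
from .mse import multiscale_entropy
from .signal_io import (
    PreprocessConfig,
    QualityConfig,
    SegmentConfig,
    preprocess,
    quality_filter,
    read_recording,
    segment_cycles,
    write_recording,
)
from .synthetic_data import CohortSpec, generate_cohort, write_truth_sidecar

__all__ = [
    "run_simulate",
    "run_extract",
    "run_mse",
    "run_stats",
    "run_classify",
    "run_all",
    "extract_recording_features",
]


def _provenance(cfg: PipelineConfig) -> dict:
    return {"config_hash": config_hash(cfg), "seed": cfg.seed,
            "pulsewave_version": __version__}


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    prov = _provenance(cfg)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# provenance={json.dumps(prov, sort_keys=True)}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path: Path, stage_hint: str) -> pd.DataFrame:
    if not path.exists():
        raise PipelineError(
            f"missing {path.name}; run the '{stage_hint}' stage first"
        )
    return pd.read_csv(path, comment="#")


def run_simulate(cfg: PipelineConfig) -> Path:
    """Generate a synthetic cohort: recordings, truth sidecars, cohort table."""
    out = _outdir(cfg)
    rec_dir = out / "recordings"
    rec_dir.mkdir(exist_ok=True)
    sim = cfg.simulate
    spec = CohortSpec(
        seed=cfg.seed,
        n_per_group=tuple(sim.n_per_group),
        duration_s=sim.duration_s,
        fs=sim.fs,
        noise_sd=sim.noise_sd,
        drift_amplitude=sim.drift_amplitude,
        drift_freq_hz=sim.drift_freq_hz,
        period_cv=sim.period_cv,
        subject_cv=sim.subject_cv,
    )
    subjects = generate_cohort(spec)
    rows = []
    for s in subjects:
        write_recording(s.recording, rec_dir / f"{s.subject_id}.csv")
        write_truth_sidecar(s.ground_truth, rec_dir / f"{s.subject_id}.truth.json")
        rows.append(
            {"subject_id": s.subject_id, "group": s.group, "age": s.age,
             "sex": s.sex, "bmi": s.bmi, **s.comorbidities}
        )
    _write_csv(pd.DataFrame(rows), out / "cohort.csv", cfg)
    return out / "cohort.csv"


def extract_recording_features(rec, cfg: PipelineConfig):
    """Preprocess, segment, and aggregate one recording's time-domain features.

    Cycles whose landmark chain violates the ordering invariant are
    rejected rather than aggregated. Returns the aggregate features and the
    preprocessed recording (for entropy analysis downstream).
    """
    pp = preprocess(rec, PreprocessConfig(
        lowpass_hz=cfg.preprocess.lowpass_hz,
        highpass_hz=cfg.preprocess.highpass_hz,
        filter_order=cfg.preprocess.filter_order,
    ))
    seg = segment_cycles(pp, SegmentConfig(
        min_period_s=cfg.fiducial.min_period_s,
        max_period_s=cfg.fiducial.max_period_s,
    ))
    seg = quality_filter(seg, pp, QualityConfig(
        min_period_s=cfg.fiducial.min_period_s,
        max_period_s=cfg.fiducial.max_period_s,
        min_amplitude=cfg.fiducial.min_amplitude,
        min_cycles=cfg.fiducial.min_cycles,
    ))
    per_cycle = []
    for i in range(seg.n_cycles):
        if not seg.accepted_flags[i]:
            continue
        a, b = seg.cycle_bounds(i)
        try:
            fp = detect_fiducials(
                pp.samples[a:b], pp.fs,
                w1_fraction=cfg.fiducial.w1_fraction,
                w2_fraction=cfg.fiducial.w2_fraction,
            )
        except DetectionError:
            continue
        if not fp.ordering_valid():
            continue
        per_cycle.append(compute_features(fp))
    agg = aggregate_recording(per_cycle, min_cycles=cfg.fiducial.min_cycles)
    return agg, pp


def run_extract(cfg: PipelineConfig) -> Path:
    """Extract per-subject time-domain features into the feature table."""
    out = _outdir(cfg)
    cohort = _read_csv(out / "cohort.csv", "simulate")
    rec_dir = out / "recordings"
    rows = []
    for _, subject in cohort.iterrows():
        sid = subject["subject_id"]
        path = rec_dir / f"{sid}.csv"
        if not path.exists():
            raise PipelineError(f"missing recording {path}; run 'simulate' first")
        rec = read_recording(path)
        agg, _ = extract_recording_features(rec, cfg)
        rows.append({"subject_id": sid, **agg.as_dict(), "n_cycles": agg.n_cycles})
    features = cohort.merge(pd.DataFrame(rows), on="subject_id")
    _write_csv(features, out / "features.csv", cfg)
    return out / "features.csv"


def run_mse(cfg: PipelineConfig) -> Path:
    """Append multiscale-entropy columns to the feature table."""
    out = _outdir(cfg)
    features = _read_csv(out / "features.csv", "extract")
    rec_dir = out / "recordings"
    rows = []
    for sid in features["subject_id"]:
        rec = read_recording(rec_dir / f"{sid}.csv")
        pp = preprocess(rec, PreprocessConfig(
            lowpass_hz=cfg.preprocess.lowpass_hz,
            highpass_hz=cfg.preprocess.highpass_hz,
            filter_order=cfg.preprocess.filter_order,
        ))
        feats = multiscale_entropy(
            pp.samples, max_scale=cfg.mse.max_scale, m=cfg.mse.m,
            r_factor=cfg.mse.r_factor,
        )
        rows.append({"subject_id": sid, **feats.as_dict()})
    merged = features.merge(pd.DataFrame(rows), on="subject_id")
    _write_csv(merged, out / "features.csv", cfg)
    return out / "features.csv"


def run_stats(cfg: PipelineConfig) -> Path:
    """Group comparison report over every extracted feature."""
    out = _outdir(cfg)
    features = _read_csv(out / "features.csv", "extract")
    names = [c for c in features.columns
             if c in TD_FEATURE_NAMES or c.startswith("mse") and c[3:].isdigit()]
    results = compare_groups(
        features, features["group"].to_numpy(), feature_names=names,
        alpha=cfg.stats.alpha, bonferroni=cfg.stats.bonferroni,
    )
    _write_csv(comparison_frame(results), out / "stats_report.csv", cfg)
    summary = {
        "_provenance": _provenance(cfg),
        "alpha": cfg.stats.alpha,
        "significant_omnibus": [r.feature for r in results if r.significant_omnibus],
    }
    with open(out / "stats_report.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    return out / "stats_report.csv"


def run_classify(cfg: PipelineConfig) -> Path:
    """Classifier x dataset evaluation report."""
    out = _outdir(cfg)
    features = _read_csv(out / "features.csv", "extract")
    report = compare_models(
        features, folds=cfg.classify.folds, seed=cfg.seed,
        knn_k=cfg.classify.knn_k, rf_trees=cfg.classify.rf_trees,
    )
    _write_csv(report.to_frame(), out / "classification_report.csv", cfg)
    payload = {"_provenance": _provenance(cfg), "ranking": report.ranking(),
               "folds": report.folds, "seed": report.seed}
    with open(out / "classification_report.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
    return out / "classification_report.csv"


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order and return the artifact paths."""
    return {
        "cohort": run_simulate(cfg),
        "features": run_extract(cfg),
        "mse": run_mse(cfg),
        "stats": run_stats(cfg),
        "classification": run_classify(cfg),
    }
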