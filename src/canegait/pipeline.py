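"""End-to-end orchestration: simulate → preprocess → features → stats → classify.

The whole run is a pure function of (config, seed): a single top-level
seed is expanded into named per-stage seeds, every artifact carries a
provenance header (config hash + seed), and excluded trials are
accounted for per stage so that analyzed + excluded = input always.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import run_classification
from .errors import DataError
from .features import TrialFeatures, extract_trial_features
from .io import (
    FEATURE_COLUMNS, ImuRecording, RunConfig, default_config,
    write_feature_table, write_manifest, write_trial_csv,
)
from .preprocess import (
    detect_cane_contacts, extract_analysis_window, filter_recording,
    jerk_norm, segment_cycles,
)
from .simulate import load_profile, simulate_cohort
from .stats import compare_groups


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic named sub-seed for one pipeline stage (< 2**31)."""
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([seed, tag % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class TrialDiagnostics:
    contacts: np.ndarray
    contacts_in_window: np.ndarray
    n_cycles: int


def analyze_recording(
    rec: ImuRecording, config: RunConfig | None = None
) -> tuple[TrialFeatures, TrialDiagnostics]:
    """Full single-trial chain: filter → jerk → contacts → window → features."""
    cfg = config or default_config()
    filtered = filter_recording(rec, cfg)
    jerk = jerk_norm(filtered.acc, rec.sample_rate_hz)
    contacts = detect_cane_contacts(
        jerk, rec.sample_rate_hz,
        threshold_k=cfg.contacts.threshold_k,
        min_separation_s=cfg.contacts.min_separation_s,
    )
    windowed, inside = extract_analysis_window(filtered, contacts, cfg.window_len_samples)
    cycles = segment_cycles(inside, rec.sample_rate_hz)
    feats = extract_trial_features(windowed, cycles, cfg)
    return feats, TrialDiagnostics(contacts=contacts, contacts_in_window=inside,
                                   n_cycles=len(cycles))


def build_feature_table(
    recordings,
    labels: dict | pd.DataFrame,
    config: RunConfig | None = None,
):
    """Feature rows for every analyzable trial, plus an exclusion log.

    ``labels`` maps trial_id → frail_label (or is a manifest frame).
    Unusable trials (no contact, too short, too few cycles) are excluded
    with a machine-readable reason, mirroring the study's exclusion of
    unmeasurable trials.
    """
    cfg = config or default_config()
    if isinstance(labels, pd.DataFrame):
        labels = dict(zip(labels["trial_id"], labels["frail_label"]))
    rows, exclusions = [], []
    for rec in recordings:
        if rec.trial_id not in labels:
            raise DataError(f"trial {rec.trial_id!r} has no label in the manifest")
        try:
            feats, _ = analyze_recording(rec, cfg)
        except DataError as exc:
            exclusions.append({"trial_id": rec.trial_id, "subject_id": rec.subject_id,
                               "reason": type(exc).__name__, "detail": str(exc)})
            continue
        rows.append({"trial_id": rec.trial_id, "subject_id": rec.subject_id,
                     "frail_label": labels[rec.trial_id], **feats.as_dict()})
    table = pd.DataFrame(rows, columns=["trial_id", "subject_id", "frail_label",
                                        *FEATURE_COLUMNS])
    return table, exclusions


@dataclass
class RunRecord:
    config: dict
    config_hash: str
    seed: int
    counts: dict = field(default_factory=dict)   # stage -> {input, excluded, analyzed}
    outputs: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def check_accounting(self) -> None:
        for stage, c in self.counts.items():
            if c["analyzed"] + c["excluded"] != c["input"]:
                raise DataError(f"stage {stage}: accounting identity violated: {c}")


def run_all(
    config: RunConfig | None = None,
    out_dir: str | Path = "canegait_run",
    seed: int = 0,
    profile_name: str = "default",
    write_trials: bool = False,
) -> RunRecord:
    """Run the full synthetic-cohort analysis and write every artifact.

    Re-running with an identical (config, seed) reproduces the feature
    table and fold assignments byte for byte.
    """
    cfg = (config or default_config()).validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = f"config_hash={cfg.hash()} seed={seed}"
    record = RunRecord(config=cfg.to_dict(), config_hash=cfg.hash(), seed=seed)

    t0 = time.perf_counter()
    profile = load_profile(profile_name)
    manifest, trials, _ = simulate_cohort(profile, seed=stage_seed(seed, "simulate"))
    write_manifest(manifest, out / "manifest.csv", provenance)
    if write_trials:
        trial_dir = out / "trials"
        trial_dir.mkdir(exist_ok=True)
        for trial in trials:
            write_trial_csv(trial.recording, trial_dir / f"{trial.recording.trial_id}.csv",
                            provenance)
    record.counts["simulate"] = {"input": len(trials), "excluded": 0, "analyzed": len(trials)}
    record.timings_s["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table, exclusions = build_feature_table((t.recording for t in trials), manifest, cfg)
    write_feature_table(table, out / "features.csv", provenance)
    (out / "exclusions.json").write_text(json.dumps(
        {"provenance": provenance, "exclusions": exclusions}, indent=2))
    record.counts["features"] = {"input": len(trials), "excluded": len(exclusions),
                                 "analyzed": len(table)}
    record.timings_s["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    comparisons, normality = compare_groups(table)
    comparisons.to_csv(out / "group_stats.csv", index=False)
    normality.to_csv(out / "normality.csv", index=False)
    record.timings_s["group_stats"] = time.perf_counter() - t0
    record.counts["group_stats"] = {"input": len(table), "excluded": 0, "analyzed": len(table)}

    t0 = time.perf_counter()
    report = run_classification(table, cfg, seed=stage_seed(seed, "classify"))
    summary = report.summary_frame()
    summary.to_csv(out / "classification_summary.csv", index=False)
    per_fold = pd.concat(
        [res.per_fold.assign(model=name) for name, res in report.results.items()],
        ignore_index=True,
    )
    per_fold.to_csv(out / "classification_per_fold.csv", index=False)
    metrics_json = {
        "provenance": provenance,
        "positive_label": report.positive_label,
        "models": {
            name: {
                "fold_means": res.fold_means,
                "aggregated_confusion": vars(res.aggregated),
                "aggregated_metrics": res.aggregated_metrics,
                "pooled_auc": res.pooled_auc,
            }
            for name, res in report.results.items()
        },
    }
    (out / "classification.json").write_text(json.dumps(metrics_json, indent=2))
    record.timings_s["classify"] = time.perf_counter() - t0
    record.counts["classify"] = {"input": len(table), "excluded": 0, "analyzed": len(table)}

    record.outputs = {
        "manifest": str(out / "manifest.csv"),
        "features": str(out / "features.csv"),
        "group_stats": str(out / "group_stats.csv"),
        "classification": str(out / "classification.json"),
    }
    record.check_accounting()
    (out / "run_record.json").write_text(json.dumps(
        {"config": record.config, "config_hash": record.config_hash, "seed": record.seed,
         "counts": record.counts, "outputs": record.outputs,
         "timings_s": record.timings_s}, indent=2))
    return record
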