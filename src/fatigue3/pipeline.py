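"""End-to-end orchestration: recording -> timeline -> features -> statistics."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import EEG_BANDS, RunConfig
from .eeg import eeg_feature_table
from .fnirs import (
    denoise_long_channels,
    hemo_feature_table,
    hemodynamics_by_location,
    process_fnirs_od,
)
from .io import log_stage, write_feature_table
from .labeling import BehaviorSeries, build_timeline, compute_perclos, detect_valid_yawns
from .prv import prv_feature_table
from .stats import LMMResult, fit_lmm, make_report
from .types import MultimodalRecording, StageTimeline

#: Features analyzed on the scale reported in the field: raw for EEG
#: relative powers and the beta ratio, normalized for hemodynamics and PRV.
def analysis_feature_columns() -> list[str]:
    cols = []
    for base in [f"rpl_{b}" for b in EEG_BANDS] + ["eta"]:
        for loc in ("fp1", "fpz", "fp2", "chavg"):
            cols.append(f"{base}_{loc}")
    for feat in ("hbo", "hbr", "hbt", "coe"):
        for loc in ("fp1", "fpz", "fp2", "chavg"):
            cols.append(f"m_{feat}_{loc}_norm")
    cols += ["sdnn_norm", "rmssd_norm"]
    return cols


def behavior_series(rec: MultimodalRecording) -> BehaviorSeries:
    """PERCLOS blocks and valid yawns from the raw behavioral streams."""
    perclos, times = compute_perclos(rec.behavior.eye_state, rec.behavior.eye_rate_hz)
    return BehaviorSeries(perclos, times, detect_valid_yawns(rec.behavior.yawns))


def label_recording(rec: MultimodalRecording, config: RunConfig | None = None) -> StageTimeline:
    """Three-level stage timeline for one session."""
    config = config or RunConfig()
    tl = build_timeline(rec.behavior.fisa, behavior_series(rec), config.windows)
    log_stage("label", subject=rec.subject_id, n_intervals=len(tl.intervals))
    return tl


def process_recording(
    rec: MultimodalRecording,
    config: RunConfig | None = None,
    timeline: StageTimeline | None = None,
    modalities: tuple[str, ...] = ("eeg", "hemo", "prv"),
) -> pd.DataFrame:
    """Full per-window multimodal feature table for one session."""
    config = config or RunConfig()
    tl = timeline if timeline is not None else label_recording(rec, config)
    parts: list[pd.DataFrame] = []
    if "eeg" in modalities:
        parts.append(eeg_feature_table(rec, tl, config).set_index("window_mid_s"))
    if "hemo" in modalities or "prv" in modalities:
        od, masks = process_fnirs_od(rec, config)
        for key, m in masks.items():
            od[key] = np.where(m, np.nan, od[key])
        if "hemo" in modalities:
            od_brain = denoise_long_channels(od)
            locs = hemodynamics_by_location(od_brain, config)
            parts.append(hemo_feature_table(locs, tl, config).set_index("window_mid_s"))
        if "prv" in modalities:
            parts.append(prv_feature_table(od, tl, config).set_index("window_mid_s"))
    merged = parts[0]
    for p in parts[1:]:
        merged = merged.join(p.drop(columns=["stage"]), how="outer")
    merged = merged.reset_index()
    merged.insert(0, "subject", rec.subject_id)
    merged.insert(1, "paradigm", rec.paradigm)
    log_stage(
        "features", subject=rec.subject_id, windows=len(merged),
        missing_cells=int(merged.isna().sum().sum()),
    )
    return merged


def analyze_features(
    features: pd.DataFrame, config: RunConfig | None = None
) -> list[LMMResult]:
    """Per-paradigm, per-feature mixed models with Holm-adjusted contrasts."""
    config = config or RunConfig()
    results: list[LMMResult] = []
    usable = features[features["stage"].isin(("NonF", "ModF", "SevF"))]
    for paradigm, group in usable.groupby("paradigm"):
        for col in analysis_feature_columns():
            if col not in group.columns:
                continue
            vals = group[col].to_numpy(float)
            if np.isfinite(vals).sum() < 10:
                continue
            try:
                res = fit_lmm(
                    vals,
                    group["stage"].to_numpy(),
                    group["subject"].to_numpy(),
                    feature=col,
                    paradigm=str(paradigm),
                    cfg=config.stats,
                )
            except ValueError:
                continue
            results.append(res)
    return results


def run_experiment(
    out_dir: str | Path,
    paradigms: tuple[str, ...] = ("active", "passive"),
    n_subjects: int = 11,
    seed: int = 0,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Simulate cohorts, extract features, fit the stage models, write reports."""
    from .synthetic import simulate_cohort

    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for k, paradigm in enumerate(paradigms):
        cohort = simulate_cohort(n_subjects, paradigm, seed=seed + 7919 * k)
        for rec, _truth in cohort:
            frames.append(process_recording(rec, config))
    features = pd.concat(frames, ignore_index=True)
    feat_path = write_feature_table(features, out / "features.tsv")
    results = analyze_features(features, config)
    report_path = make_report(results, out / "stats")
    return {"features": feat_path, "report": report_path}
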