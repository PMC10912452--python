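"""End-to-end orchestration: simulate -> detect -> features -> profiles ->
clinical mixed models, with every intermediate table persisted as
delimited text and a machine-readable JSON run report.

One seed governs the whole run; per-block seeds are derived from it inside
the cohort simulator, so a (config, seed) pair reproduces the report
byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import replace

import numpy as np
import pandas as pd

from . import clinical as clin
from . import detection, factor, kinematics, signal_io
from .config import RunConfig
from .synthetic import THERAPY_STATES, SyntheticCohort, simulate_cohort

__all__ = ["run_pipeline", "build_feature_tables", "build_clinical_table"]


def _state_label(med: str, stim: str) -> str:
    return f"{med}/{stim}"


def _detection_config(config: RunConfig, movement_type: str) -> detection.DetectionConfig:
    preset = detection.PRESETS[movement_type]
    return replace(
        preset,
        rms_percentile=config.rms_percentile or preset.rms_percentile,
        jerk_percentile=config.jerk_percentile or preset.jerk_percentile,
        prominence_sd=config.prominence_sd,
        min_peak_distance_ms=config.min_peak_distance_ms,
        merge_gap_ms=config.merge_gap_ms,
        min_event_duration_ms=config.min_event_duration_ms,
    )


def build_feature_tables(
    cohort: SyntheticCohort, config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Detect events in every block and compute trial + block features.

    Returns (single-trial table, block-feature table, exclusion log).
    Block features carry the mixed-model decrement slopes; blocks whose
    detection yields < 2 events, or that fail the amplitude-clip artifact
    screen, are excluded and logged.
    """
    config = config or RunConfig()
    trial_rows: list[dict] = []
    block_rows: list[dict] = []
    exclusions: dict = {"artifact_clip": 0, "too_few_events": 0}
    for subj, med, stim, mtype, trace, _truth in cohort.iter_blocks():
        if signal_io.clip_artifact_flag(trace, config.clip_bound):
            exclusions["artifact_clip"] += 1
            continue
        det_cfg = _detection_config(config, mtype)
        filtered = signal_io.highpass_filter(trace)
        mag = signal_io.vector_magnitude(filtered)
        jerk = signal_io.jerk_series(mag)
        events = detection.detect_events(trace, det_cfg)
        if len(events) < 2:
            exclusions["too_few_events"] += 1
            continue
        feats = [kinematics.event_features(mag, jerk, e) for e in events]
        imis = kinematics.inter_movement_intervals(events)
        base = dict(
            subject=subj.subject_id,
            med_state=med,
            stim_state=stim,
            state=_state_label(med, stim),
            movement_type=mtype,
        )
        for i, f in enumerate(feats):
            trial_rows.append(
                base
                | dict(
                    event_index=f.event_index + 1,  # 1-based trial number
                    norm_accel_magnitude=f.norm_accel_magnitude,
                    jerk_mean=f.jerk_mean,
                    duration_ms=f.duration_ms,
                    imi_ms=float(imis[i - 1]) if i >= 1 else np.nan,
                )
            )
        bf = kinematics.block_features(feats, imis)
        block_rows.append(base | bf.as_dict())

    trial_table = pd.DataFrame(trial_rows)
    block_table = pd.DataFrame(block_rows)

    # decrement slopes per subject x state x movement type from the
    # random-slope models over trial number
    for feature, target in (
        ("norm_accel_magnitude", "accel_slope"),
        ("imi_ms", "imi_slope"),
    ):
        slopes = kinematics.kinematic_slopes(trial_table, feature)
        slope_map = {
            (r.subject, r.med_state, r.stim_state, r.movement_type): r.slope
            for r in slopes.itertuples()
        }
        block_table[target] = [
            slope_map.get((r.subject, r.med_state, r.stim_state, r.movement_type), np.nan)
            for r in block_table.itertuples()
        ]
    return trial_table, block_table, exclusions


def build_clinical_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """One row per subject x therapy state with derived clinical scores."""
    rows = []
    for subj in cohort.subjects:
        for med, stim in THERAPY_STATES:
            record = subj.clinical[(med, stim)]
            subtype, ratio = clin.subtype_classify(record)
            rows.append(
                dict(
                    subject=subj.subject_id,
                    med_state=med,
                    stim_state=stim,
                    state=_state_label(med, stim),
                    updrs3_total=record["updrs3_total"],
                    item_3_4_right=record["items"]["3.4"]["right"],
                    item_3_6_right=record["items"]["3.6"]["right"],
                    brady_right_sum=clin.bradykinesia_sum(record, "right"),
                    brady_left_sum=clin.bradykinesia_sum(record, "left"),
                    laterality_index=clin.laterality_index(record),
                    subtype=subtype,
                    subtype_ratio=ratio,
                )
            )
    return pd.DataFrame(rows)


def _profile_stage(
    block_table: pd.DataFrame, movement_type: str, config: RunConfig
) -> tuple[pd.DataFrame, dict]:
    sub = block_table[block_table["movement_type"] == movement_type].reset_index(
        drop=True
    )
    features = sub[list(kinematics.BLOCK_FEATURE_NAMES)].dropna(axis=1, how="all")
    features = features.dropna()
    sub = sub.loc[features.index]
    coded = factor.reverse_code(features)
    criteria = factor.FitCriteria(
        rmsea_max=config.rmsea_max,
        cfi_min=config.cfi_min,
        srmr_max=config.srmr_max,
    )
    model = factor.prune_features(
        coded,
        loading_threshold=config.loading_threshold,
        criteria=criteria,
        fit_gated=config.fit_gated_pruning,
    )
    anchor = (
        "accel_mean" if "accel_mean" in model.retained_features else None
    )
    scores = factor.profile_scores(coded[model.retained_features], anchor=anchor)
    out = sub[["subject", "med_state", "stim_state", "state"]].copy()
    out["movement_type"] = movement_type
    out["profile"] = scores.scores.to_numpy()
    info = {
        "n_obs": int(model.n_obs),
        "retained_features": model.retained_features,
        "loadings": [round(float(v), 6) for v in model.loadings],
        "removal_trail": [[f, round(v, 6)] for f, v in model.removal_trail],
        "chi_square": round(model.chi_square, 6),
        "df": model.df,
        "p_value": round(model.p_value, 6),
        "rmsea": round(model.rmsea, 6),
        "cfi": round(model.cfi, 6),
        "srmr": round(model.srmr, 6),
        "criteria_met": bool(model.criteria_met),
        "variance_explained_pct": round(scores.variance_explained_pct, 4),
    }
    return out, info


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a synthetic cohort; returns the report."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"config": config.as_dict(), "stages": {}}

    cohort = simulate_cohort(n_subjects=config.n_subjects, rng_seed=config.rng_seed)
    report["stages"]["simulate"] = {
        "n_subjects": cohort.n_subjects,
        "n_blocks": sum(len(s.blocks) for s in cohort.subjects),
    }

    trial_table, block_table, exclusions = build_feature_tables(cohort, config)
    report["stages"]["features"] = {
        "n_trials": int(len(trial_table)),
        "n_blocks": int(len(block_table)),
        "exclusions": exclusions,
    }
    _save(trial_table, config.out_dir, "single_trial_features.tsv")
    _save(block_table, config.out_dir, "block_features.tsv")

    # therapy-state models of single-trial metrics, per movement type
    report["stages"]["state_models"] = {}
    for mtype in config.movement_types:
        sub = trial_table[trial_table["movement_type"] == mtype].rename(
            columns={"event_index": "trial"}
        )
        metric_results = {}
        for metric in ("norm_accel_magnitude", "imi_ms", "jerk_mean"):
            model = clin.lme_single_trial(sub, metric)
            fstat, ndf, ddf, p = model.term_tests["state"]
            posthoc = clin.tukey_posthoc(model)
            metric_results[metric] = {
                "F": round(fstat, 4),
                "ndf": ndf,
                "ddf": round(ddf, 2),
                "p": round(p, 6),
                "emmeans": {k: round(v, 5) for k, v in model.emmeans.items()},
                "tukey": posthoc.round(5).to_dict("records"),
            }
        report["stages"]["state_models"][mtype] = metric_results

    # factor-analytic movement profiles, per movement type separately
    profiles = []
    report["stages"]["profiles"] = {}
    for mtype in config.movement_types:
        prof, info = _profile_stage(block_table, mtype, config)
        profiles.append(prof)
        report["stages"]["profiles"][mtype] = info
        state_means = prof.groupby("state")["profile"].mean()
        report["stages"]["profiles"][mtype]["state_mean_profile"] = {
            k: round(float(v), 5) for k, v in state_means.items()
        }
    profile_table = pd.concat(profiles, ignore_index=True)
    _save(profile_table, config.out_dir, "movement_profiles.tsv")

    # clinical prediction models
    clinical_table = build_clinical_table(cohort)
    _save(clinical_table, config.out_dir, "clinical_records.tsv")
    report["stages"]["clinical"] = _clinical_models(
        profile_table, clinical_table, config
    )

    report_path = os.path.join(config.out_dir, "run_report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _clinical_models(
    profile_table: pd.DataFrame, clinical_table: pd.DataFrame, config: RunConfig
) -> dict:
    out: dict = {}
    wide = profile_table.pivot_table(
        index=["subject", "state"], columns="movement_type", values="profile"
    ).reset_index()
    merged = clinical_table.merge(wide, on=["subject", "state"], how="inner")
    orphans = len(clinical_table) - len(merged)
    out["join"] = {"n_rows": int(len(merged)), "n_orphans": int(orphans)}

    if "finger_tapping" in merged.columns:
        data = merged.rename(columns={"finger_tapping": "profile"})
        for outcome, item_col in (
            ("updrs3_total", None),
            ("item_3_4_right", "item_3_4_right"),
        ):
            model_data = data
            removed = 0
            if item_col is not None:
                model_data, removed = clin.exclude_item4_observations(data, item_col)
            model = clin.lme_profile_on_updrs(model_data, outcome)
            out[f"tapping_on_{outcome}"] = _model_summary(model, removed)

    if {"finger_tapping", "pronation_supination"} <= set(merged.columns):
        data = merged.rename(
            columns={
                "finger_tapping": "tap_profile",
                "pronation_supination": "rot_profile",
            }
        )
        model = clin.lme_profile_on_updrs(
            data,
            outcome="brady_right_sum",
            profile_cols=("tap_profile", "rot_profile"),
            covariates=("laterality_index",),
            interactions=(("tap_profile", "rot_profile"),),
        )
        out["bradykinesia_model"] = _model_summary(model, 0)
    return out


def _model_summary(model: clin.LMEFit, n_excluded: int) -> dict:
    return {
        "coefficients": {k: round(float(v), 5) for k, v in model.coef.items()},
        "terms": {
            name: {"F": round(f, 4), "ddf": round(ddf, 2), "p": round(p, 6)}
            for name, (f, _ndf, ddf, p) in model.term_tests.items()
        },
        "r2_marginal": round(model.r2_marginal, 5),
        "r2_conditional": round(model.r2_conditional, 5),
        "n_excluded_item4": int(n_excluded),
    }


def _save(table: pd.DataFrame, out_dir: str, name: str) -> None:
    table.to_csv(os.path.join(out_dir, name), sep="\t", index=False, float_format="%.9g")
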