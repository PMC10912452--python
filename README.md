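# finemotor

Time-resolved quantification of fine hand movements (finger tapping and
pronation–supination) from triaxial accelerometer recordings, with a
synthetic cohort generator standing in for patient data. The pipeline runs

1. **synthetic** — accelerometer blocks with known ground-truth events
   (burst templates, amplitude/pacing jitter, noise, drift, optional
   tremor) and a cohort of subjects tested in four medication × stimulation
   therapy states, with coupled ordinal UPDRS-style clinical records;
2. **signal_io** — trace file I/O, zero-phase 3rd-order 1 Hz high-pass
   Butterworth filter, vector magnitude, jerk, RMS envelope;
3. **detection** — two-stage single-trial event detection: per-block
   percentile thresholds on magnitude and jerk (90/95th for tapping,
   80/85th for rotations) define candidate windows, confirmed by magnitude
   peaks with prominence ≥ 2.5 × block SD and ≥ 100 ms spacing;
4. **kinematics** — per-event duration-normalized acceleration magnitude,
   mean |jerk|, inter-movement intervals, block means and coefficients of
   variation, and standardized decrement slopes over trial number from
   random-slope mixed models;
5. **factor** — iterative single-factor maximum-likelihood factor analysis
   with loading-based pruning (λ < 0.70) and fit-index reporting
   (χ², RMSEA + 90% CI, CFI, SRMR), then first-principal-component
   movement-profile scores oriented so lower = better;
6. **clinical** — symptom laterality index, bradykinesia sum scores,
   subtype ratio classification, and REML mixed models with Satterthwaite
   degrees of freedom: therapy-state effects on single-trial metrics with
   Tukey-adjusted post-hoc contrasts, and profile → UPDRS prediction models
   with Nakagawa R².

## CLI

```sh
finemotor run-all --seed 1 --out out/              # full pipeline
finemotor simulate --seed 1 --out out/ --n-subjects 20
finemotor detect --out out/ out/traces/*.tsv
finemotor features --seed 1 --out out/
finemotor profile --seed 1 --out out/ --movement-type finger_tapping
finemotor clinic --seed 1 --out out/
```

All commands accept `--config <yaml>` (unknown keys are rejected; see
`finemotor.config.RunConfig` for the schema). A run writes delimited
tables (`single_trial_features.tsv`, `block_features.tsv`,
`movement_profiles.tsv`, `clinical_records.tsv`) and a machine-readable
`run_report.json`; a (config, seed) pair reproduces the report byte for
byte.

Trace files are plain text: `#`-prefixed `key=value` metadata lines
(`sampling_rate_hz`, `subject_id`, `movement_type`, `med_state`,
`stim_state`, `hand`) followed by tab-separated `time_s ax ay az` columns.

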