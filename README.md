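# antkin

Antennal kinematics toolkit: a tested, reusable pipeline for analysing how
flying insects position their antennae under airflow and optic-flow stimuli.
It covers the full chain from digitized video landmarks to multimodal
stimulus-response characterization, together with a synthetic-data generator
that reproduces the statistical structure of such recordings so every
analysis can be exercised end to end with no external data.

## What it does

- **`antkin.geometry`** — DLT (direct linear transformation) two-camera
  calibration and 3D triangulation, inter-antennal angle (IAA) from four
  digitized landmarks, digitization-error estimation from antennal-length
  variation, and groundspeed/airspeed/windspeed vector algebra.
- **`antkin.circstats`** — circular mean/SD, and a rank-based paired
  circular test for angular displacements with exact (exhaustive sign-swap)
  or Monte-Carlo permutation p-values; ANOVA + Tukey HSD comparisons of
  labelled ΔIAA samples against each other and a hypothetical zero mean.
- **`antkin.airflow`** — steady-state binning of IAA traces by airspeed,
  plateau normalization, 4-parameter sigmoid fitting, and detection of the
  dynamic airspeed region via stepwise paired circular testing across bees
  (Holm-corrected).
- **`antkin.opticflow`** — per-bee saturation-threshold detection for
  temporal-frequency responses, transition prediction from a threshold
  change-detection rule, observed-change classification, prediction scoring,
  scrambled-data significance, low-range graded response, and sinusoid
  tracking.
- **`antkin.multimodal`** — regime-based ΔIAA antagonism analysis,
  constant-cue offset classification (adaptation / uniform offset /
  nonuniform), and crossmodal speedometer calibration (optic-flow gain vs
  absolute airspeed, with extrapolating speed estimator).
- **`antkin.synth`** — generative bee profiles (baseline set point, airflow
  sigmoid, optic-flow change-integrator with saturation threshold and
  adaptation, wrapped-Gaussian frame noise, per-epoch drift), stimulus
  protocol builders, IAA trace simulation, two-camera landmark projection
  with ground truth, and constant-groundspeed free-flight trajectories.
- **`antkin.pipeline` / `antkin.cli`** — configuration-driven experiment
  orchestration with deterministic, config-hashed JSON summaries.

## CLI

The `antkin` console script (or `python -m antkin.cli`) exposes:

```sh
antkin simulate linear_ramp_air --outdir out --seed 1 --fps 500 --with-geometry
antkin reconstruct out/landmarks.csv out/calibration.json --out out/iaa.csv
antkin analyze-airflow out/trace.csv out/protocol.json --out out/airflow.json
antkin analyze-opticflow out/trace.csv out/protocol.json --out out/opticflow.json
antkin analyze-multimodal regime_covariation --seed 1 --out out/multimodal.json
antkin report --experiment tethered_airspeed_ramp --seed 1 --outdir results
```

Named experiments: `tethered_airspeed_ramp`, `free_flight_groundspeed`, `opticflow_random_sequence`,
`opticflow_ramp_threshold`, `opticflow_low_range`, `opticflow_sinusoid`, `regime_covariation`,
`constant_cue_offset`, `crossmodal_calibration`. Re-running an identical config
produces a byte-identical summary.

## File formats

All interchange is plain text: protocols and summaries as JSON, traces as
CSV (`time_s, iaa_deg, epoch, windspeed_mps, tf_cps`), landmarks as CSV
(`frame, camera, landmark ∈ {LB, LT, RB, RT}, x_px, y_px`) with schema
validation and per-line error reporting, calibrations as JSON (11 DLT
coefficients + residual per camera). Angles are degrees, speeds m/s,
temporal frequency cycles/s (cps), coordinates mm.
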