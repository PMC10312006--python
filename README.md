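# pupilwave

Analysis pipeline for dyadic pupillometry: preprocessing of raw binocular
60 Hz pupil recordings into baseline-corrected pupil-diameter-change (ΔPD)
waveforms, and detection of between-group significance windows via
consecutive pointwise one-tailed Welch t-tests calibrated by a Monte Carlo
AR(1) run-length null. A synthetic dyad-recording generator makes the whole
analysis runnable with no external data.

## What it does

1. **simulate** — generate raw binocular eye-tracker recordings (60 Hz,
   AR(1) tonic drift, light-reflex transient, correlated per-eye noise,
   binocular blink gaps, optional group-level ΔPD offsets) and write them
   as tab-separated files.
2. **preprocess** — eye-to-eye OLS regression imputation and averaging,
   60→10 Hz downsampling, strict >75 % missingness exclusion (trial and
   participant level), 11-sample rolling median filter, linear blink
   interpolation, and baseline correction over the [0.5, 1.0) s window.
3. **compare** — Welch t-test (Satterthwaite df) at every timepoint between
   two groups' ΔPD waveform matrices; the minimal run length of
   consecutively significant timepoints (pointwise α = 0.1) that controls
   the family-wise error at 0.05 is calibrated by simulating Gaussian AR(1)
   null waveforms at the autocorrelation estimated from the data. Detected
   windows are reported with start/end seconds, peak-|t| summary statistics
   and Cohen's d.
4. **analyze** — per-participant mean-ΔPD summaries, one-way and two-way
   (Type II) ANOVAs, and Holm-adjusted pairwise Welch post hoc tests.

## CLI

```bash
# end-to-end demo on synthetic data
pupilwave run-all --config examples/demo.yaml --out scratch/demo_run

# or stage by stage
pupilwave simulate   --config examples/demo.yaml --out scratch/sim
pupilwave preprocess --in scratch/sim/raw.tsv --dialect native --out scratch/pp
pupilwave compare    --in scratch/pp/clean.csv --groups parent,child \
                     --tail A_less --out scratch/cmp
pupilwave analyze    --in scratch/pp/clean.csv --out scratch/stats
```

Raw input is TSV (`native` schema, or `tobii`-style exports where validity
codes ≤ 1 count as valid). Outputs are tidy CSV (clean ΔPD, pointwise
statistics, ANOVA tables) and JSON reports (exclusions, significance
windows, config echo + hash). Runs are deterministic under a fixed config
and seed.

## Package layout

- `pupilwave.simulate` — synthetic recording generator (`simulate_trial`,
  `simulate_study`).
- `pupilwave.preprocess` — cleaning chain and exclusion bookkeeping.
- `pupilwave.waveform` — pointwise Welch tests, run-length null
  (`null_max_run`, `exact_max_run_tail`, `run_threshold`), window
  extraction, `compare_groups`.
- `pupilwave.anova` — scalar group analyses.
- `pupilwave.io` — TSV/CSV/JSON adapters (native + Tobii dialects).
- `pupilwave.cli` — Click command-line driver (`run_pipeline`).
- `pupilwave.validation` — self-validation experiments used by the
  acceptance suite and report script.
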