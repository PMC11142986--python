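# coregload

Co-registered EEG + eye-tracking analysis of cognitive load, as a tested,
reusable Python pipeline — plus a synthetic-session generator that provides
ground truth for every stage.

The analysis reproduces a fixation-related EEG workflow: two data streams
(multichannel EEG at 1000 Hz, binocular eye tracking at 250 Hz) are
synchronized through shared stimulus triggers, gaze events (blinks,
saccades, fixations) are detected with an adaptive velocity threshold, the
EEG is FIR-filtered, ocular artifacts are removed by ICA, the data are
average-referenced and cut into 2-s epochs (stimulus-locked or locked to
fixations on a picture area of interest), band power (theta 4–6 Hz, alpha
8–13 Hz) is estimated with a Hanning-tapered 500-ms sliding FFT on a
0.125-Hz grid, and condition effects are expressed as ERD/ERS% against
per-subject global condition baselines.  The statistics layer provides
repeated-measures ANOVA with Greenhouse–Geisser correction and partial eta
squared, Holm-corrected paired post hocs, per-electrode sign-flip
permutation tests with Benjamini–Hochberg FDR, repeated-measures
correlation, and Morey within-subject SEMs.

Because no participant data are available, the package ships a first-class
simulator (`coregload.synth`) that generates sessions with known structure:
1/f EEG background plus band-limited theta (frontal-max) and alpha
(parietal-max) noise carriers with per-condition power multipliers, blink
and saccade EOG transients with a frontal projection, fixation–saccade gaze
traces over text/picture areas of interest, pupil traces with load-dependent
offsets and blink dropouts, and jittered trigger tables in both streams.
Every pipeline stage is tested against this ground truth.

## Layout

| module | role |
| --- | --- |
| `coregload.synth` | ground-truth session simulator + analytic power/ERD oracles |
| `coregload.sync_io` | TSV interchange I/O, trigger-based synchronization, stream merging |
| `coregload.gaze` | blink interpolation, adaptive saccade detection, fixations, AOI metrics |
| `coregload.clean` | zero-phase FIR filtering, ocular ICA, average reference, epoching, ±100 µV rejection |
| `coregload.spectral` | sliding-FFT band power, ERD/ERS%, pupil summaries |
| `coregload.stats` | rm-ANOVA (GG), Holm, permutation + BH-FDR, rmcorr, within-subject SEM |
| `coregload.pipeline` | end-to-end orchestration with provenance logging |

## CLI

```bash
coregload simulate --seed 3 --out session/          # write a synthetic session
coregload sync --eeg session/eeg.tsv --et session/et.tsv \
    --eeg-events session/eeg_events.tsv --et-events session/et_events.tsv \
    --max-jitter 3 --out merged/
coregload events --et session/et.tsv --aoi aoi.json --out events/
coregload run --config run.yaml --seed 7 --out results/
```

`run` accepts a YAML config; every method parameter (epoch length, rejection
threshold, window/spacing, bands, detector lambda, alpha level) is exposed
with its canonical default.  Given fixed seeds, reruns are byte-identical.

Example `run.yaml`:

```yaml
analysis: both          # stimulus | fixation | both
apply_ica: true
n_perm: 2000
sim:
  n_subjects: 20
  seed: 7
  condition_power_multipliers:
    CC: {alpha: 0.8}
```

## Interchange formats

Recordings are TSVs with `#rate` / `#labels` / `#units` header lines and one
row per sample; event tables are TSVs with `sample`, `label` and a JSON
`attributes` column.  The pupil channel uses `0.0` as the blink dropout
sentinel.  Ground truth is written as a TSV event list plus a JSON sidecar
with expected band powers and the imposed stream offset.
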