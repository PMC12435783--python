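# speechtrf

Forward temporal response function (TRF) analysis of selective auditory
attention in a competing-speaker EEG paradigm, as a tested, reusable
pipeline:

* **Stimulus regressors** — word/phoneme onset impulse trains from
  time-aligned annotations (TSV or a minimal TextGrid interval dialect),
  and the speech envelope (|Hilbert| → zero-phase order-4 Butterworth
  low-pass at 8 Hz → resample to the EEG rate).
* **Encoding models** — lagged (0–500 ms) ridge regression from regressors
  to multichannel EEG, leave-one-trial-out cross-validation, λ tuning on a
  10⁻⁶…10⁶ grid by cross-validated MSE, and prediction accuracy as the
  Pearson correlation restricted to *valid* samples (0–500 ms after an
  onset).
* **Permutation null** — duration-preserving shuffles of the onset
  regressors (word durations, inter-onset intervals, and within-word
  phoneme offsets are preserved as exact multisets) refit across subjects
  to build chance-level distributions of TRFs and accuracies.
* **Group statistics** — accuracy-ranked (optionally bilateral-symmetric)
  channel selection, a running-t cluster-based permutation test on
  attend-minus-ignore difference TRFs, Wilcoxon rank-sum tests against
  chance, and signed-rank model comparisons with Benjamini–Yekutieli FDR
  correction.
* **Synthetic ground truth** — a two-stream competing-speaker simulator
  (log-normal word durations, stick-broken phonemes, P1/P2/N2-like
  kernels, attention gain, 1/f-like noise at a configurable SNR) so every
  stage is testable end to end with no external data.

## CLI

```bash
# full synthetic analysis with the default desk-scale configuration
speechtrf run-all --config config.yaml --seed 1 --out out/

# individual stages
speechtrf simulate --config config.yaml --out out/     # annotations + EEG containers
speechtrf features --annotations ann.tsv --wav speech.wav --fs 500 --duration 60 --out feats.csv
speechtrf fit --config config.yaml --out out/
speechtrf permute --config config.yaml --out out/ --n-perm 100
speechtrf stats --config config.yaml --out out/
speechtrf report --out out/
```

A configuration file (YAML or JSON) mirrors `speechtrf.pipeline.RunConfig`;
every default matches the reference analysis where one exists (lags
0–500 ms, λ grid 10⁻⁶–10⁶, 100 regressor permutations, cluster-forming and
corrected α = 0.001, 12 selected channels). Example:

```yaml
mode: synthetic
sim:
  n_subjects: 20
  n_trials: 6
  trial_duration_s: 60.0
  fs: 500.0
  n_channels: 16
  snr_db: 0.0
n_perm: 100
n_perm_cluster: 2000
out_dir: out
```

Real recordings are supported through `mode: real` with per-subject
entries pointing at an EDF file or the CSV+JSON EEG container, annotation
TSVs per condition and trial, and optional WAVs for envelope extraction.

Outputs are plain TSV/JSON under `out/` (`fits/`, `chance/`, `stats/`)
plus a `manifest.json` with parameter echoes, wall-clock times, and
SHA-256 hashes of every product; identical config + seed reproduces
identical hashes.

## Layout

```
src/speechtrf/
  features.py      annotation tiers, onset regressors, envelope, statistics
  synthetic.py     two-stream simulator with ground-truth kernels
  trf.py           lagged ridge models, CV, valid-sample scoring, λ tuning
  permutation.py   duration-preserving shuffles, chance distributions
  stats.py         channel selection, cluster test, rank tests, BY
  pipeline.py      config-driven orchestration and reporting
  io.py            EEG containers (CSV+JSON, EDF), result tables
  cli.py           command-line interface
```
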