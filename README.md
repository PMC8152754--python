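# vigildecode

Multivariate decoding of auditory salience from epoched EEG across
vigilance states (wake, NREM sleep stages N1–N3, REM), with temporal
generalization within and between states, forward-model scalp
topographies in µV, and nonparametric group statistics.

## Who this is for

Sleep/cognition researchers who want to ask, from multi-subject epoched
EEG with binary condition labels (e.g. familiar vs. unfamiliar voice,
own vs. other name): *can the condition be decoded at each latency
within a vigilance state, and does a decoder trained in one state
transfer to another* — i.e., do two brain states share a neural code
for stimulus salience? Because raw recordings for this paradigm are
rarely shareable, the package ships a synthetic-data generator that
emulates the relevant data structure (173-channel montage, 250 Hz,
state-specific background spectra, a fronto-central biphasic evoked
difference), so the entire pipeline is testable end to end.

## The method

For trials x = (x₁ … x_C) at time t, an L2-regularized logistic
regression (C = 1) is fit per timepoint:

    ŵ_t, b̂_t = argmin ½‖w‖² + Σᵢ log(1 + exp(−yᵢ (w·xᵢ(t) + b)))

The temporal generalization matrix scores each trained model at every
test latency, `TGM[i, j] = accuracy(ŵ_i, b̂_j-applied-at-time-j)`:
two-fold stratified CV within a state, plain train-on-all /
test-on-all transfer between states. Trials are conditioned first
(1–20 Hz FIR band-pass → crop −0.2…1.0 s → decimate ×4 → balance 100
epochs/condition → 25 Hz low-pass → per-trial standardization).

Weights are converted to interpretable activation patterns via the
backward→forward transform, a_t = Σ_t ŵ_t / √(ŵ_tᵀ Σ_t ŵ_t) (Σ_t:
Ledoit-Wolf training covariance), and returned to µV by reversing the
standardization. Group significance per TGM cell: two-sided
Mann-Whitney U of subject accuracies against within-subject
label-permutation nulls, Benjamini-Hochberg FDR at q = 0.01 per
state-pair matrix. See `docs/methods.md` for assumptions and numerical
details.

## Worked example

A reduced-scale simulated study — 16 subjects, states N2 and N3, a
25 µV fronto-central pattern planted in both states, 16 channels,
50 Hz sampling:

```yaml
# run.yaml
simulation:
  n_subjects: 16
  states: [N2, N3]
  n_channels: 16
  n_epochs_per_condition: {N2: 40, N3: 40}
  sfreq: 50.0
  effects:
    VOICE: {amplitude: 25.0, shared_states: [N2, N3]}
preprocessing:
  bandpass: [1.0, 7.0]
  decim: 3
  lowpass: null
  n_balance: 40
contrasts: [VOICE]
states: [N2, N3]
master_seed: 7
```

```bash
vigildecode all --config run.yaml --out results
```

prints (and writes to `results/summary.csv`):

```
contrast train_state test_state  peak_window_mean_pct  peak_window_sd_pct  n_significant_cells  max_accuracy_pct  max_accuracy_train_time_s  max_accuracy_test_time_s
   VOICE          N2         N2             96.180556            2.937098                  355         97.343750                       0.28                      0.34
   VOICE          N2         N3             74.401042            4.589844                  307         83.125000                       0.22                      0.34
   VOICE          N3         N2             90.225694            3.122118                  310         91.875000                       0.34                      0.34
   VOICE          N3         N3             78.229167            6.673897                  280         81.796875                       0.28                      0.34
```

Reading the table: `peak_window_mean_pct` is decoding accuracy averaged
over the 250–400 ms peak window (mean ± SD across the 16 subjects;
chance is 50%). The off-diagonal rows (N2→N3, N3→N2) being far above
chance shows the planted pattern *transfers* between the two states —
the shared-neural-code signature. `n_significant_cells` counts TGM
cells surviving FDR correction at q = 0.01; `max_accuracy_*` locates
the best cell, here inside the planted 250–400 ms window. The same
command writes group-mean and per-subject TGMs (`results/tgms/`),
p-value/significance maps (`results/stats/`), µV topographies
(`results/topographies/`), and figures — the matrix grid with
significance dots and interpolated scalp maps (`results/figures/`).

Stage-wise use (`vigildecode simulate | preprocess | decode | stats`)
writes and consumes intermediate bundles (NPZ + JSON sidecar; FIF
export available) so real epoched data can be substituted for the
simulated stage. Everything is deterministic given `master_seed`.

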