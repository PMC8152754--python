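# Methods

This note documents the models, defaults and numerical choices behind
`vigildecode`, and what the synthetic-data experiments do and do not
establish about real recordings.

## The analysis

The pipeline asks whether two auditory stimulus categories (familiar
vs. unfamiliar voice; own vs. other name) evoke discriminable EEG
responses within each vigilance state (WAKE, N1, N2, N3, REM), and
whether the discriminative neural code is *shared* between states.

1. **Trial conditioning.** Epoched data (trials × channels × samples,
   µV) pass through a fixed order: zero-phase windowed-sinc FIR
   band-pass 1–20 Hz on the long (−2…3 s) epochs, re-crop to the closed
   interval −0.2…1.0 s (discarding filter edge transients), decimation
   by 4 (plain sample picking — the preceding band-pass already
   confines the spectrum below the new Nyquist), balanced subsampling
   to 100 epochs per condition (both classes capped at the smaller
   count when fewer are available, so chance stays exactly 50%), then —
   at decode time — a 25 Hz FIR low-pass and per-trial, per-channel
   standardization over time samples (population SD; the removed
   mean/scale pairs are retained). Per-trial standardization makes
   every trial self-contained, so test trials never borrow training
   statistics and the transform is exactly invertible.
2. **Decoding.** One L2-regularized logistic regression (C = 1,
   intercept unpenalized) per time sample on the channel vector.
   Within a state, two-fold stratified cross-validation; each fold's
   decoders are scored at every test time on the held-out half and the
   two fold matrices are averaged, giving a temporal-generalization
   matrix (TGM) of accuracies. Across states the decoder is fit on all
   balanced training-state epochs and scored on all test-state epochs —
   the two states are disjoint recordings, so cross-validation is
   unnecessary. Decision ties (w·x + b = 0) predict class 1; this has
   measure zero on continuous data.
3. **Forward model.** A linear decoder's weights are extraction
   filters, not scalp patterns: they also load on channels whose only
   role is to cancel signal-unrelated variance. The activation pattern
   is obtained per training timepoint as Σw scaled by the latent-source
   SD, a = Σw / √(wᵀΣw), with Σ the training-data channel covariance
   (Ledoit-Wolf shrinkage toward the diagonal, stable when channels
   outnumber trials). This scaling is invariant to the arbitrary
   magnitude of w; for a clean planted source it equals that source's
   per-class deviation at the sensors. Multiplying each channel by the
   training-set mean of its per-trial standardization scales restores
   µV. Within-state maps average the two CV folds' patterns.
4. **Group statistics.** Per TGM cell, a two-sided Mann-Whitney U test
   compares the per-subject observed accuracies against per-subject
   *null* accuracies, obtained by re-running the identical decoding
   with condition labels permuted once within each subject (seeded).
   The exact U distribution is used for tie-free samples up to n = 20
   per group, otherwise the normal approximation with tie and
   continuity corrections; zero-variance cells return p = 1.
   Benjamini-Hochberg step-up correction is applied at q = 0.01 over
   the family of all cells of one (train-state, test-state) matrix.
   Two-sided testing keeps *below-chance* cells — the signature of a
   polarity-reversing code — detectable.

### Choice of the second Mann-Whitney sample

A two-sample rank test needs a comparison group. We use a
within-subject label-permutation null (one permutation per subject per
matrix family), which preserves each subject's noise spectrum, trial
count and fold structure while destroying the class information. A
one-sample Wilcoxon against 50% would be an alternative; the
permutation null was preferred because it keeps the stated two-sample
test form and is valid when per-subject accuracy distributions are
skewed.

### Granularity of the exact test

With S subjects per arm, the smallest achievable two-sided exact p is
2/C(2S, S) (≈1.6·10⁻⁴ at S = 8, ≈3.3·10⁻⁹ at S = 16). BH over a
~440-cell family at q = 0.01 sets the rank-1 threshold at ~2.3·10⁻⁵,
so at 8 subjects a rejection requires several cells jointly at the
p-floor; group-level power effectively requires the study's 16
subjects. This is why the planted-effect checks simulate 16 subjects
while the false-discovery calibration (which only needs the null
behavior) uses 8. The same discreteness makes the procedure
conservative under the global null.

## The synthetic generator

Real recordings for this paradigm are not publicly deposited, so every
stage is exercised on a generator that emulates the *statistical
structure* the analysis assumes:

* **Geometry.** Channels on a unit head disc (+y anterior) in a
  deterministic sunflower spiral; default 173 channels, matching a
  256-electrode net with cheek/neck channels removed. The true net
  geometry is not modelled.
* **Background activity** per state, independent across channels:
  1/f¹ pink noise (frequency-domain shaping of white noise, unit
  sample SD, scaled per state), one state-characteristic random-phase
  oscillation — WAKE 10 Hz alpha (4 µV), N1 7 Hz (2.5 µV), N2 13 Hz
  spindle band (3 µV), N3 1.5 Hz slow waves (15 µV), REM 6 Hz theta
  (2.5 µV) — and 2 µV white sensor noise. Pink SDs: 8/9/10/18/8 µV for
  WAKE/N1/N2/N3/REM. These magnitudes are ordinary for scalp EEG band
  power and give N3 the heaviest in-band noise, as in real sleep data.
* **Evoked class difference.** A Gaussian spatial profile (spread 0.45
  disc units) centred fronto-centrally at (0, 0.35), times a smooth
  biphasic envelope: zero before stimulus onset, maximal in the
  250–400 ms window, one sign change at 0.6 s, then a negative lobe
  recovering toward zero — a K-complex-like wave. The envelope is a
  monotone piecewise-cubic (PCHIP) through shape knots, so the zero
  crossing is unique by construction. The difference (default 5 µV for
  the voice contrast in {N2, N3}; 3 µV for the name contrast in
  {WAKE, N3}) is added to the deviant class (unfamiliar voice / other
  name), which carries the larger response in this paradigm.
* **Between-subject variability.** Log-normal amplitude jitter
  (σ = 0.2) and Gaussian topography-center jitter (SD = 0.2 × spread),
  constant across states within a subject, emulating effects that are
  unevenly distributed across subjects.
* **Trial counts.** Default 120 available epochs per condition per
  state except N1 (40), so the 100-epoch balancing cap and the
  "use-all-available" branch are both exercised. The real per-state
  counts after artifact rejection are unknown; these are placeholders.

Everything is a deterministic function of (seed, subject, state,
contrast) through `numpy` `SeedSequence` substreams, so subjects and
blocks are independent and bit-reproducible regardless of execution
order.

**What the generator does not emulate:** volume-conducted spatial
correlation of background noise (channels are independent; a mixing
matrix would be a one-line extension), realistic K-complex morphology,
eye/muscle artifacts, within-recording state transitions, or serial
dependence between trials. Passing tests therefore demonstrate the
*machinery* (calibration, power against planted structure, unit
recovery), not performance on real sleep EEG.

## Reduced problem sizes

The calibration experiments use scaled-down problems chosen so the
statistics of interest are unchanged:

* **Chance-level control:** 16 subjects, 8 channels, 100 epochs per
  condition, zero effect amplitude, the full 250 Hz conditioning chain
  (76×76-cell TGMs). Channel count does not affect the chance level;
  8 channels keep covariance estimation and fitting fast.
* **False-discovery control:** 500 independent global-null repetitions
  at 8 subjects, 8 channels, 20 epochs per condition, 50 Hz
  acquisition with a 1–7 Hz band-pass and decimation ×3 (~21×21-cell
  matrices). At this sampling rate the 25 Hz decode-time low-pass is
  vacuous and is skipped. Filtering is applied to all subjects of a
  repetition in one stacked call — the FIR acts per trial, so this is
  numerically identical to per-subject calls.
* **Planted-pattern recovery:** 16 subjects, 4 states, amplitude set
  to 3× the largest per-sample background SD among the carrying states
  (the detectability condition under which the group machinery is
  expected to have power; N3's slow-wave noise sets the scale).

## Numerical choices and edge cases

* Logistic fits use exact Newton iterations (`newton-cholesky`);
  the objective is strictly convex so solver choice affects speed
  only. Non-convergence raises rather than warns.
* Zero-variance trial-channels standardize to all-zeros with scale 1
  (flagged), keeping the transform invertible.
* The closed crop interval keeps both endpoint samples (301 samples
  for −0.2…1.0 s at 250 Hz; 76 after decimation by 4).
* Balanced subsampling draws class 0 then class 1 without replacement
  from a seeded generator and restores chronological order.
* µV recovery through per-trial standardization is approximate: when
  the evoked signal dominates a trial's variance, the per-trial scale
  itself depends on the signal and compresses recovered magnitudes.
  At realistic SNR (noise-dominated scales) recovered peak magnitudes
  agree with the planted per-class deviation to within ~25%; the exact
  noiseless single-timepoint identity is verified separately.
* The BH family is one state-pair matrix (matching the per-matrix
  significance dots of the standard presentation); a global family
  over all pairs would be stricter and is a caller-side change.

## Known limitations

* Cross-state transfer is asymmetric by construction (train A → test B
  need not equal B → A); no symmetry is asserted or assumed.
* The permutation null uses one permutation per subject rather than a
  full permutation distribution; this is what makes the two-sample
  Mann-Whitney form possible at study scale, but it adds Monte-Carlo
  noise to the null arm.
* Statistical testing of topographies is deliberately absent —
  patterns are descriptive.
* With fewer than ~12 subjects the exact-test granularity discussed
  above makes the group-level procedure very conservative.
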