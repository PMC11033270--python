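# Methods

## Pipeline overview

The analysis decodes binary mental workload (low vs. high) from multichannel
EEG via directed connectivity features:

1. **Cleaning** — 1 Hz zero-phase high-pass, narrowband line-noise removal,
   simplified artifact subspace reconstruction (ASR), average re-reference.
2. **Windowed MVAR** — 6-s windows slid with a 4-s step; per-window VAR(p)
   by per-equation least squares after mean removal; order by AIC
   (`AIC(p) = N_eff · ln det Σ̂(p) + 2pM²`) over 1..12, or a fixed global
   order for reproducibility studies; diagnostics: Ljung–Box residual
   whiteness (worst channel, lags 1..20), consistency percentage
   (`100·(1 − ‖R_data − R_model‖_F / ‖R_data‖_F)` over lag-0..20 correlation
   matrices of the window vs. an equally long simulation from the fitted
   model), and companion-matrix stability. Diagnostics are advisory: they are
   logged and can exclude windows via a config flag, but never silently drop
   data.
3. **dDTF** — `A(f) = I − Σ A_k e^{−i2πfk/fs}` on a 1–50 Hz grid (1 Hz
   spacing), `H = A⁻¹`, `S = HΣH*`; dDTF = full-frequency-normalised DTF ×
   coherence magnitude; band averages over delta/theta/alpha/beta/gamma.
4. **Hierarchical selection** — per-connection single-feature LDA AUC under
   stratified 7-fold CV, top-30 per band pooled to 150 candidates; then
   forward selection (wrapper, ε-improvement stop), mRMR (MID, 10
   equal-frequency bins) and Relief-F (k = 10 neighbours, min-max scaled
   distances) on equal footing (the filters default to the wrapper's subset
   size).
5. **Classification** — stratified 7-fold CV of SVM (RBF, C = 1,
   gamma = 'scale'), LDA, random forest (100 trees), decision tree, all
   behind per-fold standardisation; metrics in percent from per-fold
   confusion matrices (positive class = high workload), reported mean ± sd.

## Evaluation protocol and selection leakage

One-seventh of the window samples is held out (stratified); ranking,
selection and the reported cross-validation all run on the remaining
six-sevenths, and the held-out split provides a final confirmation score.

Selecting the top connections by AUC on the same samples that the
cross-validation folds are drawn from inflates accuracy: at desk scale
(hundreds of windows, 910 candidate connections) a null dataset evaluates at
60–78% under that naive protocol. The reported per-band and pooled CV numbers
therefore **nest the AUC ranking inside each fold** (`crossval_evaluate_ranked`):
features are re-ranked on the k−1 training folds only, so the held-out fold
never influences selection and a true null sits at chance. The
selector-comparison table keeps the conventional fixed-subset protocol (the
selectors run once on the training partition); its numbers are comparative,
and the held-out test accuracy is the unbiased check for that stage.

Window samples inherit their recording's label, and windows of one subject
can land in both training and validation folds. Because the generator draws
subject individuality once per subject (shared by both conditions), subject
identity carries no label information; with real data, subject-grouped folds
are the conservative alternative.

## Synthetic study conditions

The generator emulates the STEW geometry: 14 channels at 128 Hz named after
the 10–20 montage, one recording per condition per subject. The frozen study
conditions (`make_study_dataset`) are:

| parameter | value | rationale |
|---|---|---|
| subjects × conditions | 12 × 2 | desk-scale stand-in for the corpus's 48 × 2 |
| duration | 90 s | 22 windows per recording (528 samples total) |
| VAR order | 6 | long enough for band-resonant coupling kernels |
| self-coupling | 0.35 (geometric lag decay) | stable broadband autocorrelation |
| edge coupling | 0.7 before rescaling | clear but not saturating contrast |
| differential edges | 6, gain ratio 2× in high workload | the class contrast |
| edge resonances | 3, 6, 10, 20, 40, 6 Hz (damped cosine, λ = 0.85) | one edge per band: bands carry complementary information, as band-specific workload signatures do in real EEG |
| companion radius | rescaled to ≤ 0.92 | stationary but slowly mixing |
| subject jitter | ±10% multiplicative, drawn per subject, shared across conditions | non-identical CV folds without labelable recording fingerprints |
| sensor noise | 10 µV white (equal to innovation scale) | prevents any single band from saturating |

Uniform rescaling to the target companion radius preserves the coupling
topology and relative edge strengths. Innovations are Gaussian with identity
covariance — the standard MVAR assumption. Artifact bursts (square-windowed
0.5–3 Hz transients, 500 µV, on a random half of the channels) are available
to exercise the cleaning stage and are off by default in the study
conditions.

What the generator does **not** emulate: 1/f background spectra, alpha
rhythms, volume conduction, non-Gaussian artifacts, electrode drift.
Passing tests therefore demonstrate correctness of the estimation and
selection machinery on VAR ground truth, not performance on real EEG.

## Numerical choices

- **Sign convention.** The characteristic matrix is `A(f) = I − Σ A_k z^k`;
  an overall sign flip changes nothing downstream because every dDTF factor
  is magnitude-based.
- **Coherence basis.** The coherence factor uses the plain spectral matrix
  (`|S_ij|/√(S_ii S_jj)`, unsquared), the printed form of the measure; a
  `partial` mode computes partial coherence from the inverse spectral matrix
  (the variant that suppresses indirect cascades harder). The complex
  cross-spectrum enters through its magnitude — the only convention that
  makes the factor real and bounded.
- **Average-reference rank deficiency.** Re-referencing removes the channel
  common mode, so the regressor matrix of a subsequent VAR fit is exactly
  rank-deficient. The fit tolerates precisely that null space (minimum-norm
  solution, unique on the data subspace) and still raises a singular-fit
  error for any other deficiency, e.g. duplicated channels.
- **ASR simplification.** Calibration is the RMS-quietest contiguous stretch
  (10 s default); processing is per 0.5-s block; per-block principal
  components whose std exceeds `cutoff_k` (default 20) × the
  calibration-projected std are attenuated to the threshold and the block is
  reconstructed. No block demeaning (a local mean is artifact-contaminated
  inside a burst). Samples are never dropped, so window counts stay
  deterministic. Parity with the published ASR implementation is a non-goal.
- **Notch design.** The notch is designed at half the nominal width because
  forward-backward filtering squares the response; default 50 Hz, width
  1 Hz (narrow, because the gamma band ends at the line frequency at
  fs = 128); harmonics above Nyquist are skipped. The line frequency is
  configurable (60 Hz supported below Nyquist).
- **Degenerate single-feature LDA.** With zero within-class variance the 1-D
  discriminant reduces to orienting the feature by the training-fold mean
  difference; the AUC scorer falls back to that limit instead of failing.
- **Fast ranking.** Ranking all 910 connections uses a vectorised
  rank-statistic identity (held-out single-feature LDA AUC equals the
  tie-corrected Mann–Whitney AUC of the feature oriented by the
  training-fold mean difference); the per-column LDA implementation is kept
  as the reference and the two agree to machine precision (unit-tested).
- **Ties.** Top-k ties at the cut break by lexicographic (band, source,
  target) order; AIC ties prefer the smaller order — both make reruns
  byte-identical.
- **Forward-selection stop.** ε-improvement rule (ε = 1e−4 on the accuracy
  fraction) with a hard cap; candidates whose evaluation degenerates (e.g.
  constant columns) are skipped.
- **Self-connections** are computed but excluded from all feature tables;
  exports label edges `source⇒target`.

## Problem sizes

Tests and the acceptance script run desk-scale versions of the study:
6–12 subjects, 40–90 s recordings, and 20–100-replicate simulation studies
for the estimator checks (coefficient recovery at T = 10⁴ over 20 seeds, AIC
order recovery at T = 768 over 50 seeds, directed recovery over 100 window
fits). The full-corpus geometry (48 subjects, 150 s → 3,552 samples × 910
features) is exercised for its arithmetic (window counts, tensor shapes,
pool sizes) rather than re-simulated end to end.

## Known limitations

- The dDTF's frequency normalisation makes values grid-dependent; compare
  values only across identical grids.
- Whiteness and consistency thresholds are advisory; the consistency statistic
  depends on a simulation seed and has sampling noise of a few percentage
  points on 6-s windows.
- The reference flow table shipped with the package is a fixed published
  listing used for region bookkeeping; it is not recomputed from data here.
- EDF I/O is not implemented; recordings are exchanged in the STEW
  whitespace-delimited text dialect with a JSON sidecar.
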