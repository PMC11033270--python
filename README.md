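# eegflow

Directed EEG connectivity analysis for mental-workload (MWL) classification.

Cognitive workload changes how brain regions drive one another. This package
implements a complete, testable version of a workload-decoding pipeline built
on *effective* (directed) connectivity: multichannel EEG is segmented into
sliding windows, each window is fitted with a multivariate autoregressive
(MVAR) model, the model is transformed into the frequency domain to obtain
the **direct directed transfer function (dDTF)** in five canonical bands
(delta 2–4, theta 4–8, alpha 8–13, beta 13–32, gamma 32–50 Hz), and the
resulting directed band-connectivity values are used as features in a
hierarchical selection scheme (per-connection LDA AUC ranking, then forward
selection / mRMR / Relief-F) feeding cross-validated classifiers (SVM, LDA,
random forest, decision tree).

It targets the geometry of the open STEW corpus (48 subjects, 14 channels at
128 Hz, 2.5 min per condition, low vs. high workload) and ships a synthetic
two-class VAR-EEG generator with known directed couplings, so every stage —
cleaning, estimation, connectivity, selection, classification — is verifiable
against ground truth without downloading any data.

## The measure

For a window modelled as a VAR(p), `x_t = Σ_k A_k x_{t−k} + u_t`, the
characteristic matrix on a frequency grid is `A(f) = I − Σ_k A_k e^{−i2πfk/fs}`,
the transfer matrix is `H(f) = A(f)⁻¹`, and the spectral density matrix is
`S(f) = H(f) Σ H(f)*`. The dDTF from channel *j* to channel *i* multiplies a
full-frequency-normalised DTF factor by a coherence factor:

```
dDTF_ij(f) = |H_ij(f)|² / (Σ_f Σ_k |H_ik(f)|²)  ×  |S_ij(f)| / √(S_ii(f) S_jj(f))
```

The first factor sums over the whole grid, so it totals exactly 1 per target
row; the second is bounded by Cauchy–Schwarz, so dDTF ∈ [0, 1]. Values are
averaged over the grid frequencies inside each band, giving a
`windows × bands × channels × channels` connectivity tensor per recording
(37 × 5 × 14 × 14 at the STEW geometry: 150 s, 6-s windows, 4-s steps).

## Worked example

```python
import eegflow as ef

# two-class dataset under the package's frozen study conditions:
# 12 subjects x 2 conditions, 90 s at 128 Hz, 14 channels, 2x coupling
# gains on six band-resonant edges in the high-workload class
ds = ef.make_study_dataset(seed=1)

tensors = [ef.connectivity_for_recording(r, ef.ConnectivityConfig(order=6))
           for r in ds.recordings]
table = ef.feature_table(tensors)          # 528 window-samples x 910 features

# pooled top-30-per-band SVM accuracy, AUC ranking nested in each CV fold
pooled = ef.crossval_evaluate_ranked(table, ef.ModelSpec("svm", seed=1), 7, 1)
print(pooled.summary()["accuracy"])        # -> 95.83% (+/- 1.79)

alpha = ef.crossval_evaluate_ranked(table, ef.ModelSpec("svm", seed=1), 7, 1,
                                    band="alpha")
print(alpha.summary()["accuracy"])         # -> 91.11% (+/- 2.35)
```

Pooling the five bands beats the best single band because each band carries a
complementary part of the class contrast — the generator couples the classes
differently at band-specific resonances, which is also the qualitative pattern
this style of analysis reports on real workload EEG. A label permutation
collapses the pooled accuracy to ~50%, confirming the signal is not a
selection artifact.

The same analysis is available from a shell:

```
eegflow simulate --subjects 12 --duration 90 --seed 1 --out data/
eegflow run-all --seed 1 --skip-preprocess --out results/
```

`run-all` writes the ranked-connection table, per-region connection counts,
per-band/pooled/per-selector classification tables and the selection traces
as CSV, plus a JSON summary.

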