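# mbeeg

Decoding five-class finger motor imagery from EEG with a multi-branch
GAT-GRU-Transformer, with built-in phase-locking connectivity and
Shapley-value interpretability.

## Who this is for

Researchers working on motor-imagery brain–computer interfaces who want
a fully testable, CPU-scale implementation of a three-branch EEG
decoder — spatial (graph attention over the electrode montage),
temporal (GRU + Transformer encoder), and frequency (per-band 1-D CNNs)
— together with the analysis tooling around it: a preprocessing
pipeline, phase-locking-value (PLV) connectivity, classification
metrics with McNemar model comparison, an ablation harness, and a joint
attribution–connectivity report. A bundled synthetic EEG generator with
known ground truth (class-dependent event-related desynchronisation at
C3/C4/Cz, configurable inter-channel phase coupling, 1/f background)
makes every stage testable without downloading any data.

## The model

Each preprocessed trial **X ∈ ℝ^{C×T}** (C = 22 channels, T = 256
samples: 2 s at 128 Hz) passes through three parallel branches:

- **Spatial** — node features per electrode, a hierarchical graph
  attention network over an adjacency **A** (distance-thresholded,
  PLV-percentile, or hybrid distance×PLV; PLV edge weights act as a
  log-prior inside the attention softmax):
  low-level layers give H_low ∈ ℝ^{C×D_low}, the high-level layer gives
  F_spatial ∈ ℝ^{C×D}.
- **Temporal** — the sample sequence through a unidirectional GRU
  (hidden D′ = 128), learnable temporal embeddings, and a pre-norm
  Transformer encoder: F_time ∈ ℝ^{T×D″}.
- **Frequency** — Delta/Theta/Alpha/Beta/Gamma band split, each band
  through a depthwise-then-mixing 1-D CNN stack (kernels 5 and 3,
  stride 1, ReLU, max-pooling): F_freq of width D‴.

Fusion: F_pool = GAP(Concat(F_spatial, F_time, F_freq)) ∈ ℝ^{D+D″+D‴},
then a 1-D-conv + dense head produces the five class logits.

Connectivity uses PLV = |T⁻¹ Σ_t exp(i·ΔΦ(t))| on analytic-signal
phases of band-passed epochs. Attribution uses permutation-sampling
Shapley values over channel coalitions (efficiency exact per sample)
or gradient×input; band importance is measured by band-content
replacement. Everything runs on an in-package NumPy autodiff engine —
no deep-learning framework required.

## Worked example

```python
import numpy as np
from mbeeg import SynthSpec, generate_epochs, plv_matrix
from mbeeg.bands import band_by_name
from mbeeg.train_eval import ContingencyTable, mcnemar

# 50 trials of synthetic motor-imagery EEG with full C3-C4 Beta coupling
spec = SynthSpec(
    n_trials_per_class=10, seed=0, snr=6.0,
    erd_channels={}, coupling_pairs=(("C3", "C4", "Beta", 1.0),),
)
epochs = generate_epochs(spec)   # bandpass -> 128 Hz -> epoch -> z-score
print(f"epochs: {epochs.n_trials} trials x {epochs.n_channels} channels "
      f"x {epochs.n_times} samples at {epochs.fs:g} Hz")

m = plv_matrix(epochs, band_by_name("Beta", epochs.fs))
idx = epochs.montage.index
print(f"Beta PLV C3-C4 (coupled):    {m.values[idx('C3'), idx('C4')]:.3f}")
print(f"Beta PLV O1-Fp2 (uncoupled): {m.values[idx('O1'), idx('Fp2')]:.3f}")

res = mcnemar(ContingencyTable(a=280, b=62, c=38, d=120))
print(f"McNemar: chi2 = {res['statistic']:.2f} (p = {res['p_value']:.4f}), "
      f"corrected chi2 = {res['statistic_corrected']:.2f} "
      f"(p = {res['p_value_corrected']:.4f})")
```

This prints:

```
epochs: 50 trials x 22 channels x 256 samples at 128 Hz
Beta PLV C3-C4 (coupled):    0.926
Beta PLV O1-Fp2 (uncoupled): 0.187
McNemar: chi2 = 5.76 (p = 0.0164), corrected chi2 = 5.29 (p = 0.0214)
```

The fully coupled pair reads a PLV near 1 (the residual gap is Beta-band
background noise), the uncoupled distant pair sits at the finite-sample
noise floor (~0.19 at T = 256 averaged over 50 trials), and the McNemar
example shows both statistic variants on a paired-classifier
contingency table: 62 vs 38 discordant predictions over 500 test items
is significant at p < 0.05, i.e. the first classifier's advantage is
unlikely to be chance.

The same flows are scriptable from the shell:

```
mbeeg simulate --out rec.h5 --seed 0
mbeeg preprocess --in rec.h5 --out epochs.h5
mbeeg connectivity --in epochs.h5 --band Beta --out plv_beta.csv
mbeeg run --out runs/demo --seed 0     # full pipeline incl. training + report
mbeeg mcnemar --a 280 --b 62 --c 38 --d 120
```

`mbeeg run` trains the full model on a generated dataset and writes a
prediction report (confusion matrix, accuracy, per-class
precision/recall/F1) and a joint attribution–connectivity report
(top channels by Shapley value, band importances, PLV submatrices and
their concordance with the attribution ranking).

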