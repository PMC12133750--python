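# Methods

## Problem setting

`mbeeg` decodes five-class finger motor imagery from multichannel EEG.
The classifier is a three-branch network — graph attention over the
electrode montage (spatial), GRU + Transformer encoder over the sample
sequence (temporal), and per-band 1-D CNNs over a filter bank
(frequency) — whose branch features are global-average-pooled,
concatenated, and mapped to class logits by a small 1-D-conv + dense
head. Interpretability couples Shapley-value attribution of the
trained model with phase-locking-value (PLV) connectivity.

## Preprocessing

Fixed stage order: 4th-order Butterworth bandpass 0.5–100 Hz applied
forward–backward (zero phase; amplitude follows the *squared* magnitude
response) → polyphase resampling 1000 → 128 Hz (event indices rescaled
with round-half-even; an off-by-one here would shift epoch content) →
optional ICA artifact rejection → 2-s epochs from −0.5 s to +1.5 s
around each trigger (256 samples at 128 Hz) → per-(trial, channel)
z-scoring with population standard deviation.

Zero-phase filtering was chosen because phase distortion would corrupt
PLV estimates downstream. Z-scoring is applied per trial and channel
after epoching, making trials comparable and removing electrode-gain
differences; it also makes total per-channel variance uninformative, so
class information survives only as *relative* (band-wise and temporal)
power structure — intentional, and mirrored by the synthetic task.

Artifact rejection decomposes the recording with FastICA (fixed seed,
hence deterministic) and zeroes components that either correlate with a
frontal channel above 0.8 (ocular surrogate) or have excess kurtosis
above 8 (spiky/muscular surrogate). Because the bundled generator
produces no ocular or muscular sources, the pipeline wrapper runs this
stage opt-in; it is fully implemented and tested on recordings with an
injected frontally-loaded blink source.

Note the band-limit interaction: after resampling to 128 Hz the Nyquist
frequency is 64 Hz, so the Gamma band is capped at 0.98 × Nyquist ≈
62.7 Hz; 64–100 Hz content present before resampling is unrepresentable
afterwards. The stage order (filter, then resample) follows the
processing pipeline the model is defined for, and the loss is accepted
and documented.

## Connectivity and the adjacency graph

Instantaneous phase is the analytic-signal angle of the band-passed
trace. PLV between two channels is |mean unit phasor of the phase
difference|, computed per trial over the full epoch (T = 256) and
averaged across trials; the estimator's noise floor for independent
phases scales as ~sqrt(pi)/(2 sqrt(T)) ≈ 0.06 per trial. Matrices are
symmetric with unit diagonal by construction.

Three adjacency builders feed the spatial branch: binary
distance-thresholding (edge iff electrode distance < d; d defaults to
0.35 montage units on the unit-sphere head model), PLV-percentile
thresholding (keep pairs at or above the 75th percentile of
off-diagonal PLV, weighted or binarized), and the default **hybrid**:
the distance mask multiplied by PLV weights, i.e. local anatomical
support carrying a synchrony prior. Positive edge weights enter the
attention softmax as additive log-priors, so a stronger PLV edge
multiplies the unnormalised attention mass of that neighbour; binary
edges contribute log 1 = 0 and reduce to plain masked attention.
Self-loops are always present — attention over a node's neighbourhood
must include the node itself. The Beta band is the default prior band
(motor-relevant synchrony); a mean-over-bands option exists.

## Network

All layers run on an in-package reverse-mode autodiff engine
(`mbeeg.autodiff`) written on NumPy; gradients are verified against
central finite differences in the test suite. Initialisation is
Glorot-uniform from the config seed; a model built twice from one seed
is bit-identical, and training is deterministic given the train-spec
seed (single-threaded NumPy).

- **Spatial branch.** Each channel's time course is linearly projected
  to a d_low = 16 node feature; two low-level GAT layers (4 heads,
  concatenated, LeakyReLU(0.2) scoring and activation) model local
  inter-channel interactions, and one high-level layer (heads averaged,
  no output activation) produces C × D with D = 32. Attention is
  LeakyReLU-scored additive attention masked to the adjacency.
- **Temporal branch.** The trial is read as a T-step sequence of
  C-dimensional channel vectors, optionally average-pooled along time
  by `temporal_pool` (a speed/resolution trade; default 1), through a
  unidirectional GRU (hidden D′ = 128 by default), learnable additive
  temporal embeddings, and a pre-norm Transformer encoder stack
  (2 layers, 4 heads, feed-forward 256), then projected to T × D″.
  Zero-initialised gate biases give the contract that an all-zero
  input produces an all-zero GRU state.
- **Frequency branch.** The trial is split into Delta/Theta/Alpha/
  Beta/Gamma by an ideal (brick-wall) FFT band mask — a self-adjoint
  linear operator, so its autodiff backward pass is itself. Each band
  runs a **depthwise temporal convolution (kernel 5, per channel)**
  followed by a channel-mixing convolution (kernel 3), each with ReLU
  and max-pool 4, stride 1 throughout; band outputs concatenate to a
  D‴ = bands × conv_channels feature map. The depthwise-first order is
  deliberate: a channel-mixing first layer averages the per-channel
  band amplitudes that carry the class signal into near-chance
  features (measured by a linear probe: 0.24 vs 0.91 accuracy on
  pooled features), whereas the depthwise layer preserves them — the
  standard temporal-then-spatial factorisation of EEG CNNs.
- **Fusion and head.** Each branch is global-average-pooled over its
  non-feature axes, concatenated to a vector of length D + D″ + D‴,
  passed through dropout, a 1-D convolution (kernel 3) across the
  feature vector, and a dense layer to 5 logits. Any branch can be
  ablated; the fusion width shrinks accordingly, and the
  "no-Transformer" ablation keeps the GRU.

Training minimises cross-entropy with Adam (default lr 1e-3, batch 32)
plus optional decoupled (AdamW-style) weight decay; splits are
stratified 80/20 by default.

Three optional training-time mechanisms address an interference mode
we observed on desk-scale data (a branch with high memorisation
capacity can drive the joint loss to zero before the generalising
branch's features mature, freezing validation accuracy at chance):

- **auxiliary supervision** (`aux_weight`): a linear classifier per
  branch adds a weighted cross-entropy on each branch's pooled
  features, keeping discriminative gradient flowing to every branch
  after the fusion loss saturates; auxiliary heads are ignored at
  inference;
- **modality dropout** (`branch_dropout`): whole pooled branch vectors
  are dropped per batch (survivors rescaled), so the fusion head
  cannot rely on a single branch;
- **frequency warm-up** (`warmup_epochs` + `finetune_lr_factor`): the
  head first trains with only the frequency branch's features (other
  branch slots zero-filled), then all branches train jointly at a
  reduced learning rate — standard pretrain-then-fine-tune staging.

All three default to off; the end-to-end synthetic check uses
aux 0.3, modality dropout 0.3, a 25-epoch warm-up, and a 0.1
fine-tune factor over 40 total epochs.

## Synthetic study conditions

The generator emulates a 22-channel 10–20 montage at 1000 Hz with 4-s
cue-based trials (trigger 1 s into the trial, 0.5-s inter-trial gaps)
and exactly balanced classes. Each channel is 1/f Gaussian noise
(exponent 1, RMS 10 µV) plus five narrow-band oscillators (random-walk
phase around each band's centre; relative base amplitudes
Delta 1.0 / Theta 0.8 / Alpha 1.0 / Beta 0.7 / Gamma 0.4, scaled so
total oscillation RMS = snr × noise RMS). Class identity is a
multiplicative Beta-band amplitude factor (default 0.5) applied
post-trigger at class-specific electrode subsets: C3 / C4 / Cz /
C3+C4 / C3+C4+Cz for classes 1–5 — contralateral/midline ERD
patterns with exactly class-neutral pre-trigger baselines. Phase
coupling injects a shared band oscillator into both channels of a
configured pair in proportion to the coupling strength, giving a PLV
ground truth (C3–C4 Beta at 0.8 by default).

What the generator does **not** emulate: volume conduction / forward
head-model mixing, real artifact morphology (blinks, EMG beyond
broadband noise), inter-subject variability, and non-stationary
background spectra. Passing tests therefore demonstrate that the
pipeline recovers the *kind* of structure motor-imagery decoding relies
on (band-limited, spatially focal power modulation and phase
synchrony), not performance on real recordings.

## Attribution

Two backends share the Shapley-axiom contract. The reference is
permutation-sampling Shapley with channels as players: a coalition's
value is the model's predicted-class probability when coalition
channels carry the trial and the rest carry the background mean
(training-set mean epoch by default). The estimator satisfies
efficiency exactly for every sample (marginal contributions telescope),
and matches exact coalition enumeration and the linear-game closed
form at toy scale. gradient×input is the fast approximation. Channel
Shapley values are spread uniformly over the channel's time axis in the
per-element report so per-trial sums are preserved.

Band importance is measured by perturbation — swap one band's spectral
content for the background's and record the drop in predicted-class
probability — because the model consumes broadband input and band
decomposition happens inside the frequency branch; importances are
probability drops in [−1, 1]. The joint report ranks channels by mean
|attribution|, extracts the top-k PLV submatrix per band, and scores
concordance as the Spearman correlation between a top channel's
attribution and its mean PLV to the other top channels; constant ranks
are reported as an explicit null, not zero.

## Numerical choices and degenerate inputs

Zero-variance (trial, channel) pairs are an error in z-scoring, named
by trial and channel. Epoch windows are half-open sample ranges with
round-half-even index mapping. Degenerate all-equal PLV matrices keep
all edges with a warning. Softmax is computed with max-shift
stabilisation; attention masks are additive −1e9 terms. McNemar's
b = c = 0 case returns statistic 0, p = 1 with a warning. Metrics for a
class absent from both truth and prediction are NaN and flagged, never
silently 0.

## Problem sizes used by the test suite

Unit and property tests run on toy tensors and epoch sets of 20–50
trials. The end-to-end learning check trains a reduced-width
configuration (GRU hidden 32, one Transformer layer, temporal pooling
4, 16 conv maps per band) on 200 trials/class; the ablation harness
contract runs two-epoch trainings on the small session fixture. These
sizes are the package's own choice of desk-scale defaults; all widths
are config-exposed.

## Known limitations

The spatial and temporal branches carry little generalisable signal
under the synthetic conditions (the class feature is band-power
structure, which the frequency branch extracts most directly — a
frequency-branch-only model reaches ~0.93 test accuracy on the
standard task while unstaged joint training of the full model stalls
near chance); the staged training schedule above exists for exactly
this regime. On real
EEG — with volume conduction, channel covariance structure, and
event-locked temporal dynamics — the relative contribution of the
branches will differ. PLV estimated on 256-sample epochs has a
non-negligible noise floor; uncoupled pairs read ~0.1–0.2, not 0.
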