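# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the open design decisions behind `emofuse`.

## Signal model and preprocessing

A trial is a 32-channel scalp potential time series in µV.  The channel
set is the 32-electrode 10–20 cap common in consumer affect studies,
with positions stored as classic spherical angles and flattened to the
unit disc by azimuthal-equidistant projection (`emofuse.montage`).  The
frontal group {Fp1, Fp2, AF3, AF4, F3, F4, F7, F8, Fz} is the region
where β activity is expected to rise with emotional activation.

Preprocessing runs per trial:

1. **Denoising** — per-channel discrete wavelet transform (db4, level
   4), soft shrinkage of all detail bands by the universal threshold
   λ = σ√(2 ln L), with σ estimated from the median absolute deviation
   of the finest details (σ = MAD/0.6745).  λ = 0 reduces to identity
   up to reconstruction round-off, which the tests assert.
2. **Segmentation** — non-overlapping windows of duration T (default
   0.2 s, i.e. 5 frames/s alignment with the expression stream); the
   trailing remainder is dropped.  Windows must contain at least 32
   samples, so the default sampling rate is 256 Hz.  Band energies are
   computed per segment without overlap; overlapping estimation is a
   configuration away but not the default.
3. **Band energies** — Welch PSD integrated over θ 4–8, α 8–13, β
   13–30 Hz (conventional edges).  Energy scales quadratically with
   amplitude; a pure 10 Hz tone lands ≥95% of its power in α.  At the
   default 51-sample windows the spectral resolution is coarse (~5 Hz),
   which is sufficient for band-level contrasts but not for narrow-band
   work.
4. **Topography** — the 32 per-band energies are interpolated to a
   32 × 32 image.  Both interpolants (Clough–Tocher cubic, default, and
   piecewise linear) are linear in the electrode values, so the map is
   precomputed once as a 32 × (H·W) weight matrix by interpolating the
   canonical basis vectors.  Pixels outside the electrode hull are
   masked to zero; each electrode's nearest pixel carries its measured
   value exactly and belongs to the mask; cubic images are clipped to
   the electrode [min, max] range so interpolation never overshoots the
   measurements.
5. **Descriptors** — SIFT-style gradient-orientation histograms on a
   fixed 5 × 5 keypoint grid with 8 × 8 support.  The standalone
   descriptor (`build_feature_matrix`) defaults to the classic 4 × 4
   subcells × 8 orientations = 128 dims with per-row L2 normalisation.
   The pipeline uses 2 × 2 × 8 = 32 dims, unnormalised, followed by a
   fixed elementwise compression `log1p(d/4) − 1`.  The fixed constants
   are a nominal calibration for scalp maps of a few tens of µV²; the
   transform is band-local and trial-independent *by design*: any
   adaptive (per-trial) normalisation would move label information
   between bands and corrupt attention-localization experiments in
   which only one band is informative.

## Networks

**BCN.** Input is an M × N feature matrix.  Left projection (N_l
channels of M′ × M matrices, summed over input channels) recombines
keypoints; right projection (N_r channels of N × N′) re-projects and
reduces the descriptor space; a multichannel 1-D convolution along each
row is max-pooled in non-overlapping windows and activated as
F = tanh(b_c + Q); two fully connected layers produce the feature
vector (a softmax head is optional).  Pipeline defaults are small
(N_l = N_r = 2, M′ = 12, N′ = 16, 4 conv channels of length 5, pool 2,
48-unit hidden layer, 24-dim features); one BCN is shared across the
three EEG bands, a second serves the expression stream.

**Attention.**  Band attention computes per-segment softmax importances
over (α, β, θ) features from logits ω_i·h_{n−1} + b_i, where h_{n−1} is
the previous hidden state of the EEG stream's forward AM-LSTM; the
fused feature then passes a tanh FC layer to give the per-segment EEG
input.  The temporal gate is a sigmoid (bands compete via softmax;
vector components are weighted independently in (0,1)), and the gated
input feeds standard LSTM gate equations.  The gate uses two distinct
matrices for the input and recurrent terms.  Dropout on the hidden
state uses the inverted convention (mask entries 0 or 1/(1−p)), so
evaluation needs no rescaling.

**Fusion.**  Layer 1: one bidirectional attention-gated LSTM per
stream (hidden 16 per direction; the backward EEG direction consumes
the per-segment inputs produced by the forward band-attention loop).
Layer 2: per-step sigmoid-linear merge of the streams (24 dims).
Layer 3: a bidirectional layer over the merged sequence.  Temporal
pooling is the mean over steps; bidirectional states are concatenated.
Pooled stream and temporal features are projected (linearly) to
df = 64 and combined by subspace fusion with k = 4 subspaces;
mapping matrices and centres are trained by backprop from 0.1-scale
random initialisation.  Centres are one dk-vector per subspace.

**Classifiers and loss.**  Each supervised feature gets cosine-logit
classifiers; training uses AM-Softmax with the standard denominator
e^{s(cos−m)} + Σ_{j≠y} e^{s cos}.  The total loss sums loss_F over the
stream features, loss_SF on the subspace-fused feature, and loss_DF on
the log of the averaged branch posteriors.  Decision fusion combines
finished decisions: its loss updates only the DF classifier weights
(the posteriors are detached).  Backpropagating loss_DF into the
features was observed, reproducibly at fixed seeds, to create a stable
degenerate equilibrium in which two classes merge while the total loss
still decreases; detaching removes the pathology without changing the
decision rule.  Predictions are the argmax of the averaged posteriors.

## Tunable parameters that matter

| parameter | default | notes |
|---|---|---|
| T (segment duration) | 0.2 s | ties EEG segments to the 5 fps expression stream |
| band edges | θ 4–8, α 8–13, β 13–30 Hz | conventional definitions |
| topo resolution / method | 32 px, cubic | linear available; both clipped to electrode range |
| AM-Softmax scale s | 12 | see below; exposed in config |
| AM-Softmax margin m | 0.35 | standard additive-margin setting |
| subspaces k / df | 4 / 64 | df must be divisible by k |
| optimiser | Adam, lr 2·10⁻³, batch 32, 25 epochs | global gradient-norm clip 5 |
| dropout p | 0.1 | inverted Bernoulli mask on hidden states |
| sequence cap | 25 segments | desk-scale ceiling per trial |

The widely quoted AM-Softmax setting s = 30 assumes a pre-trained or
large-scale embedding.  Trained jointly from scratch at this problem
scale, s = 30 made the classifier/feature co-adaptation stick in
plateaus that merge adjacent ordinal classes (loss decreasing, argmax
frozen); s ≈ 10–15 trains reliably, so the default is 12 with both s
and m exposed in configuration.

Arousal and valence are trained as **separate models** (one per
dimension) over the same extracted features.  A single shared network
with two cosine-margin heads was consistently unstable: the two
objectives fight over one embedding geometry, and each stream is also
pushed to classify the dimension it carries no information about.
Separate dimensional experiments match how results are conventionally
reported for this task.

## The synthetic generator

The generator emulates exactly the structure the method exploits, and
no more:

* **EEG** — per channel, each band contributes three random-phase
  sinusoids at random in-band frequencies, scaled so the band variance
  matches the configured power map; β amplitude is multiplied by 1.5 on
  frontal electrodes; white Gaussian noise (1 µV) is added.  The
  default arousal map is (α, β, θ) = (40, 8, 15) µV² at level 0,
  (25, 25, 15) at level 1, (8, 48, 15) at level 2: β rises and α falls
  with activation, θ is flat.  How much β rises with activation is not
  quantified anywhere authoritative; these values encode a strong,
  clearly detectable effect and are exposed in `SynthConfig`.
* **Faces** — per frame, an M × N feature matrix equal to a fixed
  valence-dependent mean pattern (unit-normal entries scaled by the
  effect size, default 1.0) plus unit noise.  Frames are sampled at
  1/T.
* **Labels** — round-robin over the 3 × 3 arousal × valence grid, so
  counts per cell differ by at most one.

Everything is deterministic given (config, trial seed), and a manifest
replays a dataset bit-for-bit.

What the generator does **not** model: ocular/muscle artifacts (beyond
white noise), inter-subject variability, volume-conduction correlation
structure between channels, nonstationarity within a trial, realistic
face appearance (features are synthesised directly in descriptor
space), and label noise.  Passing tests therefore demonstrate that the
implementation recovers the structure it targets under controlled
conditions — not that the pipeline reaches any particular accuracy on
recorded human data.

## Study sizes and evaluation

The standard synthetic study uses 300 trials, an 80/20 split, and the
default optimiser settings; training one dimensional model takes tens
of seconds on a single CPU core.  Evaluation reports RA, micro- and
macro-F1, and R² per dimension.  For the single-label multiclass task
the class-aggregated (micro) counts make every error one false positive
plus one false negative, so micro-F1 equals RA; the macro variant is
reported alongside.  R² is computed between predicted and true ordinal
levels.  The multimodal-advantage comparison trains the fused model and
both unimodal models identically (both dimensions each) and compares
mean RA across the two dimensions, which is the claim the generator
encodes: arousal lives in the EEG stream, valence in the face stream,
and only the fused model can recover both.

The attention-localization study regenerates data in which α and θ
powers are constant across arousal levels and only β varies; after
end-to-end training of the EEG stream, the mean learned β attention
exceeds the other two bands (checked over three seeds).  Per-trial
attention series are exportable as CSV.

## Numerical choices

* All computation is float64; the autodiff engine is a minimal
  tape-based design validated against central finite differences
  (stiff losses are checked at a larger step, 10⁻⁴–10⁻⁵, to stay out
  of round-off).
* Max-pooling and the max reduction route gradient to the first argmax
  on ties.
* Cosine logits add 10⁻¹² inside the norm; explicit zero-norm inputs to
  the loss functions raise errors instead.
* Non-finite training losses abort with the first non-finite stage
  named.
* Checkpoints are zip archives of per-parameter `.npy` arrays plus a
  JSON manifest of shapes and the run configuration; loading validates
  shapes.

## Known limitations

* The montage uses idealised 10–20 angles, not digitised positions.
* Welch energies on 51-sample windows trade frequency resolution for
  frame-rate alignment.
* The acceptance-scale studies run in minutes on one core; the
  architecture is deliberately small (thousands of parameters per
  model) and is not tuned for recorded corpora.
* EDF/BDF recordings are readable (`read_raw_edf`, via mne) when their
  channel names come from the supported montage; EDF *writing* is not
  implemented, and numeric NPZ archives are the native interchange
  format for raw trials.
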