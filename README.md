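# emofuse

Multimodal emotion recognition from EEG and facial expression, built
around bilinear-projection feature networks, soft attention, and a
three-layer bidirectional LSTM fusion stack trained with an
additive-margin cosine softmax objective.

## The problem

Dimensional affect models describe an emotional state by two ordinal
ratings: **arousal** (activation intensity) and **valence**
(positivity).  Physiological studies record both a 32-channel scalp EEG
and a face video while a participant watches emotion-inducing clips; the
task is to predict 3-level arousal and valence ratings per trial.  The
two signals are complementary — EEG band physiology tracks activation
(β power rises and α power falls with arousal, most visibly over the
frontal electrodes), while facial configuration tracks valence — so a
fusion architecture that preserves each stream's temporal dynamics
should beat either stream alone.

The package is aimed at researchers who want a fully testable,
dependency-light reference implementation of this pipeline.  Because the
common affect corpora are access-restricted, a first-class synthetic
generator reproduces the statistical structure the method exploits, so
every stage is exercised end to end without downloads.

## The method

**EEG branch.** Each trial is denoised per channel by wavelet soft
thresholding (db4, level 4, universal threshold λ = σ√(2 ln L)), tiled
into segments of duration *T* (1/*T* matches the face frame rate), and
summarised per segment by Welch band energies in θ (4–8 Hz), α
(8–13 Hz), and β (13–30 Hz).  The 32 per-channel energies of each band
are interpolated onto a 2-D scalp image; a grid of SIFT-style
gradient-orientation descriptors turns each image into an *M* × *N*
feature matrix.

**BCN features.** A bilinear convolution network maps a feature matrix
to a vector: a *left* multichannel projection O_t = Σ_j h_tj·I_j
recombines keypoint rows, a *right* projection O_t = Σ_j I_j·h_tj
re-projects and reduces the descriptor columns, then a multichannel 1-D
convolution along each row is max-pooled and activated,
F = tanh(b_c + Q), flattened, and passed through two fully connected
layers.

**Attention.** The three band features are fused per segment by a
softmax **band attention** θ_i ∝ exp(ω_i·h_{n−1} + b_i) driven by the
EEG stream's previous hidden state; a sigmoid **temporal gate**
a_t = σ(W_x x_t + W_h h_{t−1} + b) reweights each input component
before every LSTM step (the AM-LSTM).

**Fusion.** Layer 1 runs one bidirectional AM-LSTM per stream; layer 2
merges the streams per time step, f_t = σ(ω[h_t^expr, h_t^eeg] + b);
layer 3 models the merged sequence with another bidirectional layer.
Pooled stream features are additionally combined by **subspace fusion**:
with df = k·dk, each feature is projected into k subspaces, weighted by
a Gaussian kernel of its distance to a learned centre,
sw_ij = exp(−‖f_i SW_j − M_j‖²/df), and the weighted sums are
concatenated.

**Objective.** Every supervised feature uses AM-Softmax,

    L = −mean_i log e^{s(cos θ_{y_i} − m)} /
                   (e^{s(cos θ_{y_i} − m)} + Σ_{j≠y_i} e^{s cos θ_j}),

and the total loss is loss_F (per-stream features) + loss_SF (the
subspace-fused feature) + loss_DF (decision fusion over averaged branch
posteriors).  Reported statistics are recognition accuracy
RA = N_TP/N_data, the confusion-count F1 = 2N_TP/(2N_TP+N_FP+N_FN), and
R² = 1 − Σ(Y_act−Y_pre)²/Σ(Y_act−Ȳ)².

All networks run on a small reverse-mode autodiff engine included in the
package (`emofuse.autodiff`), validated against finite differences.

## Worked example

Generate 300 balanced synthetic trials, train the fused model (one
network per emotion dimension), and evaluate on a held-out fifth
(roughly two minutes on one CPU core):

```python
import numpy as np
from emofuse import (SynthConfig, generate_dataset, RunConfig,
                     extract_features, train, evaluate_features)

dataset = generate_dataset(SynthConfig(n_trials=300, seed=0))
config = RunConfig(seed=0)
features = extract_features(dataset, config)

rng = np.random.default_rng(0)
perm = rng.permutation(len(features))
test_idx, train_idx = perm[:60], perm[60:]

result = train(config, features.subset(train_idx))
report = evaluate_features(result, features.subset(test_idx))
for head in ("arousal", "valence"):
    r = report[head]
    print(f"{head}: RA={r['ra']:.3f}  F1_micro={r['f1_micro']:.3f}  R2={r['r2']:.3f}")
print("mean band attention (alpha, beta, theta):",
      [round(x, 3) for x in report["attention_mean"]])
```

prints

```
arousal: RA=0.983  F1_micro=0.983  R2=0.974
valence: RA=1.000  F1_micro=1.000  R2=1.000
mean band attention (alpha, beta, theta): [0.258, 0.519, 0.223]
```

Arousal is recovered almost perfectly from the EEG stream (98.3% of the
60 held-out trials; R² compares the predicted and true ordinal levels),
valence perfectly from the expression stream, and the learned band
attention concentrates on β — the band the generator ties to
activation.  The same study is scriptable from the shell:

```bash
emofuse generate --n-trials 300 --seed 0 --out data/
emofuse preprocess --data data/ --out features.npz
emofuse train --data features.npz --checkpoint model.ckpt --seed 0
emofuse evaluate --data features.npz --checkpoint model.ckpt
emofuse export-attention --data features.npz --checkpoint model.ckpt --out attn/
```

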