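# mssecnn — directed EEG coupling features and multi-scale SE-CNN classification

`mssecnn` classifies cognitive state from multichannel EEG by first turning
each recording into directed functional-connectivity matrices and then
feeding those matrices to a small convolutional classifier.  It is aimed at
researchers studying pre- vs post-training differences in spatial-cognition
EEG (or any two-condition design where the conditions differ in
inter-regional coupling rather than in band power).

## Method

**Features — permutation conditional mutual information (PCMI).**  Each
channel is reduced to ordinal patterns: the permutation sorting each
m-sample delay vector (m = 3, lag τ = 1).  Directed coupling from channel
x to channel y is the plug-in conditional mutual information on the symbol
sequences,

    PCMI(x → y) = mean over δ of  I(y_{t+δ} ; x_t | y_t)      [bits],

with prediction lags δ ∈ {1, 2} samples (8–16 ms at 125 Hz).  Computed for
every ordered channel pair within each frequency band (Delta 1–4, Theta 4–8,
Alpha1 8–10.5, Alpha2 10.5–13, Beta1 13–20, Beta2 20–30, Gamma 30–40 Hz)
and each 4 s analysis window, this yields a 16 × 16 coupling matrix per band
and a 16 × 16 × C feature tensor per window for a C-band combination.

**Preprocessing.**  Chebyshev-I bandpass 1–100 Hz, 50 Hz notch, optional
FastICA artifact removal, downsampling 1000 → 125 Hz, per-band zero-phase
decomposition, 4 s sliding windows with 2 s step.

**Classifiers.**  Four variants share one skeleton on the H × W × C tensor:
a 1 × 1 conv stem, one (3×3) or three (3×3, 5×5, 7×7) parallel conv branches
with 2 output channels each and 4 × 4 max-pooling, optional
squeeze-and-excitation channel reweighting

    Z_c = mean_{i,j} X[i,j,c],   S = σ(W₂ ReLU(W₁ Z)),   X̃[i,j,c] = S_c X[i,j,c],

then FC 512 → FC 256 → softmax.  `cnn` (single branch), `secnn` (+SE),
`mscnn` (multi-scale), `mssecnn` (multi-scale + SE).  Training: Adam,
lr 1e-4, batch 64, five-fold cross-validation; precision, recall, F1, AUC
and accuracy per fold.  The networks are implemented directly on NumPy
(float32, seeded, analytic backprop), so results are exactly reproducible.

**Synthetic data.**  Because suitable public recordings with known coupling
ground truth are scarce, the package ships a generator: each channel is a
sum of band-limited AR(2) oscillators plus broadband noise, 50 Hz line
interference and optional blink transients; directed coupling is injected as
a variance-preserving lagged mixture in a band component, and the two
classes differ only in coupling strength.

## Worked example

```bash
python examples/03_direction_recovery.py
```

```
segments: 59
PCMI(0 -> 1): 0.1012 bits  (true coupling direction)
PCMI(1 -> 0): 0.0910 bits
directionality index: +0.053
```

A 4-channel, 120 s recording couples channel 0 → 1 in the Alpha2 band with
a 10 ms lag.  Averaged over the 59 analysis windows, PCMI in the true
direction exceeds the reverse direction; the small margin reflects the
strong instantaneous correlation the band oscillation induces between the
channels.  `examples/04_train_and_compare.py` runs the four-model
cross-validated comparison on a small synthetic benchmark, and
`examples/01_*` / `02_*` demonstrate simulation and feature extraction.

A thin CLI mirrors the library (`mssecnn simulate / features / train /
evaluate / run-all`); see `mssecnn --help`.

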