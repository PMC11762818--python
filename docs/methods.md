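# Methods

This note documents the models, the estimation choices, the synthetic-data
generator, and the known limitations of the package.

## Ordinal symbolization and PCMI

A series x is mapped to ordinal patterns: the code at index t is the
lexicographic rank of the argsort permutation of
(x_t, x_{t+τ}, …, x_{t+(m−1)τ}).  Ties are broken by temporal order (the
earlier sample ranks lower); on filtered continuous EEG exact ties have
measure zero, but the fixed rule makes integer-valued test inputs
deterministic.  Permutation entropy is the Shannon entropy (base 2) of the
plug-in pattern distribution.

Directed coupling is estimated as the plug-in conditional mutual information
I(y_{t+δ}; x_t | y_t) on the symbol sequences, averaged over prediction lags
δ, from the empirical histogram of symbol triples.  Empty histogram cells
contribute zero (0·log 0 := 0); no pseudo-counts are added by default (a
`pseudo_count` option exists).  Values are reported in bits.  The estimator
is non-negative up to floating round-off; the coupling-matrix constructor
clips the ~1e−16-scale negatives to zero.

Defaults and why:

* **m = 3, τ = 1.**  A 4 s window at 125 Hz gives ~498 symbols against
  6³ = 216 histogram cells for the trivariate statistic; m = 4 (24³ cells)
  would be hopelessly sparse at this window length.
* **δ = {1, 2}.**  One to two samples at 125 Hz is 8–16 ms, the range of
  cortico-cortical conduction delays this package models (5–10 ms lags in
  the generator).  Longer prediction lags carry no directional information
  for narrowband rhythms and averaging them in dilutes the asymmetry: in
  direction-recovery experiments (one Alpha2 edge, strength 0.6, 120 s,
  30 simulation seeds) δ = {1…5} recovered the true direction in 16/30
  runs versus 30/30 for δ = {1, 2}.  All three parameters are exposed in
  `PcmiParams`.
* **Diagonal set to 0** rather than self-PCMI; self-coupling carries no
  information for the classifier.
* **No normalization of PCMI values by default.**  An optional per-tensor
  z-score (`crossvalidate(..., normalize=True)`) is available and is used by
  the benchmark protocol because it speeds Adam convergence at the fixed
  1e-4 learning rate by roughly 5× without changing converged accuracy.

PCMI is computed per 4 s segment (matching segment-level classification),
not per whole recording.

## Preprocessing

Chebyshev-I bandpass (order 4, 0.5 dB passband ripple) 1–100 Hz and a 50 Hz
second-order IIR notch (quality factor 30), both applied forward–backward:
phase distortion would bias the lag-based coupling estimates.  Downsampling
1000 → 125 Hz uses a zero-phase FIR anti-alias filter (unit DC gain,
reflection-padded edges) followed by decimation.  Band decomposition (after
downsampling) uses per-band Chebyshev-I order-4 filters; all seven canonical
bands lie below the 62.5 Hz Nyquist.  Windows are rectangular, 4 s long with
a 2 s step; the trailing partial window is dropped, so a T-second recording
yields ⌊(T−4)/2⌋+1 segments.

Artifact removal is best-effort and off by default (the synthetic data is
artifact-free unless requested): FastICA decomposes the recording, sources
whose absolute correlation with a frontal blink template (0.5–3 Hz bandpass
of the mean of the two frontal channels) exceeds 0.7 are zeroed, and the
recording is reconstructed.  On decomposition failure the input is returned
unchanged with a warning.

## Classifier variants

All variants operate on H × W × C tensors (NHWC) and share: 1 × 1 conv stem
with `stem_channels` = C outputs (the stem adjusts the band mixing without
touching spatial structure), conv branches with same padding and stride 1,
ReLU, 4 × 4 max-pool stride 4, flatten, FC 512 → FC 256 (ReLU) and a final
FC + softmax over 2 classes, trained with categorical cross-entropy.
Multi-scale variants use three branches (3×3, 5×5, 7×7, each 2 output
channels); single-scale variants use the 3×3 branch only, making
cnn/secnn/mscnn strict ablations of mssecnn.

The squeeze-and-excitation block squeezes each channel plane by global
average pooling, passes the C-vector through a biased C → C/r → C bottleneck
(ReLU, then sigmoid) and multiplies each plane by its weight.  r = 2 by
default (with 6 concatenated branch channels the common r = 16 is
impossible; C/r must be an integer ≥ 1).  SE is placed after branch
concatenation by default, with `se_placement="before_branches"` as an
alternative that reweights the stem's band planes instead; on the synthetic
benchmark the two placements perform within noise of each other.

The head reads "two fully connected layers then softmax" as FC 512 → FC 256
feeding one softmax output layer.

The networks are implemented directly on NumPy in float32 with analytic
backprop (im2col convolutions) and a standard Adam optimizer; initialization
is Glorot-uniform from a seeded generator, so builds and training runs are
exactly reproducible.  Gradient correctness is verified against central
differences in the test suite.

## Training and evaluation

Batch 64, 250 epochs, Adam with initial learning rate 1e-4.  "Iterations"
are interpreted as epochs; the config allows overriding.  An exponential
learning-rate decay (γ = 0.99 per epoch) is applied to the multi-scale
variants only.  Five-fold cross-validation is segment-level stratified by
default; a subject-level grouped scheme is available and asserts train/val
subject disjointness on every fold.  Metrics: precision, recall, F1 and
accuracy from the 0.5-thresholded class-1 probability (a tie predicts class
0), and AUC by the Mann–Whitney rank statistic with averaged ranks for ties.
Per-epoch training curves are running averages over minibatches; validation
curves are full-set evaluations.

## Synthetic-data generator

Each channel is a sum of independent noise-driven damped AR(2) oscillators,
one per band, with poles at radius r = exp(−π·bw/fs) and angle at the band's
geometric-centre frequency, where bw is half the band's width.  Tying the
oscillator bandwidth to the band keeps each component genuinely band-limited
(a fixed pole radius of, e.g., 0.97 at 1000 Hz yields a ~9.5 Hz-wide peak —
wider than most bands — so "band" components would bleed across the analysis
bands and dilute any injected coupling).  Band amplitudes default to typical
resting-EEG values (Delta 20, Theta 10, Alpha1/Alpha2 10, Beta1 5, Beta2 4,
Gamma 2 µV RMS), plus 5 µV broadband noise and a 2 µV 50 Hz line component.

A coupling edge (src → dst, band, lag, strength s) replaces the destination
band component by the variance-preserving mixture
√(1−s²)·own + s·source(t−lag), so coupling strength changes directed
dependence without changing band power — the two classes ("pre"/"post")
differ **only** in s: label "post" adds `class_effect` to every edge's
strength.  Defaults: two edges (Alpha2: ch 8 → 12, lag 10 ms, and Gamma:
ch 9 → 13, lag 5 ms), base strength 0.4 (moderate coupling), class effect
+0.3 (strong, 0.7, after training).  The label enters generation only
through the mixing coefficients: the same seed produces identical
oscillators and noise for both classes.

Blink artifacts (for exercising the ICA stage) are 1–2 Hz half-sine
transients of 100 µV on the two frontal channels, Poisson-distributed at
`artifact_rate` events per minute; off by default.

What the generator does **not** emulate: volume conduction / common sources,
non-stationarity, 1/f background spectra, realistic electrode montage
geometry, or broad-band multi-pair condition differences.  Passing tests
therefore demonstrate correctness of the pipeline and recoverability of
sparse coupling differences, not expected performance on real EEG.

## Benchmark protocol and observed ceilings

The default benchmark draws 100 balanced 4 s segments per class from 60 s
recordings (seven-band 16 × 16 × 7 tensors) and runs five-fold stratified
CV.  To fit desk-scale runtimes the protocol trains for 40 epochs with
per-tensor z-scored inputs (convergence-equivalent to much longer raw-input
training at the fixed learning rate).

With the default two-edge class difference, a single 4 s window carries
limited class information: the per-segment PCMI estimator's sampling
variance (~0.02–0.06 bits within a recording) is of the same order as the
between-class mean shift at the coupled entries.  Logistic regression given
oracle knowledge of the four informative matrix entries reaches ~0.71–0.77
accuracy across seeds, bounding what any classifier can do here; the CNN
variants reach ~0.55–0.70, with the multi-scale models consistently above
the single-branch CNN and the SE block contributing no consistent advantage
at this signal-to-noise ratio.  Stronger or more numerous coupling edges, or
longer windows, raise all of these numbers; the defaults were chosen as a
realistic sparse-difference regime and kept fixed.

## Known limitations

* The plug-in CMI estimator is biased upward at short window lengths; the
  bias largely cancels when comparing directions or classes but absolute
  PCMI values should not be compared across different window lengths.
* FastICA component rejection uses a single correlation rule against a blink
  template; muscular/cardiac artifacts are not specifically modelled.
* EDF files can be read (via MNE) but not written.
* The NumPy training loop is single-threaded; it is sized for 16 × 16
  inputs and a few hundred segments, not for large-scale training.
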