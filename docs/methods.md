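# Methods

## Pipeline model and assumptions

The package classifies fixed-length ECG beats by (i) expanding each beat
into a continuous-wavelet scalogram, (ii) extracting deep spatial features
with a small attention-gated CNN, (iii) reducing those features to a
bag-of-words histogram over a k-means vocabulary, and (iv) classifying the
histograms with a kernel SVM (kNN available for comparison). The approach
assumes beats can be cut on a fixed one-second grid without R-peak
alignment — the constant timeframe, not cardiological alignment, is the
segmentation contract — and that class identity is carried by beat-level
morphology visible in the time–frequency plane.

## Segmentation and normalisation

Records are cut into consecutive half-open windows `[iL, (i+1)L)` with
`L = round(fs · window)`, `window = 1 s` by default; a trailing partial
window is dropped, so `n_beats·L + n_dropped = n_samples` with
`0 ≤ n_dropped < L`. Beats inherit the record label (fragment-level
labelling). Each beat is z-scored (mean 0, sd 1; constant beats map to
zeros) before the wavelet transform; this removes the arbitrary mV scale
and is toggleable (`PipelineConfig.zscore_beats`).

## Scalogram

The transform is `W(a,b) = a^{-1/2} ∫ s(t) Ψ̄((t−b)/a) dt` with the
analytic Morlet (complex Morlet, bandwidth 1.5, centre frequency 1 Hz) as
mother wavelet. The wavelet family is a configuration choice: the scalogram
practice this follows never fixes one, and the analytic Morlet is the
standard pick for band-localised energy in biomedical signals. Scales are
derived from a logarithmic frequency grid, 12 voices per octave over
0.5–40 Hz by default (the ECG energy band); `freq_max` must respect
Nyquist. Evaluation is delegated to PyWavelets and converted to
continuous-time units (divide by √fs); the test-suite checks agreement with
a direct Riemann quadrature of the integral to ≤5 % relative L2 on short
beats, the residual being discretisation and edge effect, not convention.
The magnitude matrix is resized bilinearly (no anti-aliasing, for
determinism) to a square image and min–max scaled to [0,1]; a constant
image maps to all zeros by convention. Images are single-channel; an RGB
colormap rendering would add nothing but nondeterminism in colormap choice.
The inverse transform exists only as `inverse_diagnostic`, a round-trip
sanity number; the pipeline never inverts.

## Network

Layer order: conv1 → ReLU → conv2 → ReLU → maxpool(2×2) → attention gate →
conv3 → ReLU → flatten → fully connected head. All convs are 3×3, stride 1,
same padding. The reference geometry (input 256, channels 32/64/128,
17-way head) is the unique simple geometry consistent with both a
128·128·128 = 2,097,152-feature flatten and a ~36 M parameter total
(35,756,753 = 320 + 18,496 + 73,856 + 12,480 attention + 35,651,601 head).
The **SFV is the flatten output**, not the FC output: only that reading is
consistent with both printed counts; the FC layer is the training head.

The attention gate computes f, g, h by 1×1 convolution (channel-preserving,
no C/8 bottleneck — the description being followed says only "1×1
convolution"), attention rows `A_i = softmax_j f(x_i)ᵀ g(x_j)` (every row a
probability vector), output `o_i = Σ_j A_ij h(x_j)`, and gates the pooled
map multiplicatively: conv3 sees `x ⊙ o`. No learnable residual scale is
used. `attention_subsample` thins keys/values on a strided grid (default 4
at input side ≥256, 1 otherwise) to keep the N×M attention matrix tractable
at full resolution; it is exact (subsample 1) at test sizes. With the gate
disabled (ablation) conv3 sees the pooled map directly and the attention
parameters provably receive zero gradient.

Implementation is NumPy with hand-written backprop (im2col convolutions,
cached softmax attention, max-pool argmax scatter), float64 throughout;
correctness is enforced by finite-difference gradient tests over every
parameter tensor, with and without the gate and with key subsampling. One
subtlety: the bias of g has exactly zero gradient (a per-row constant shift
is annihilated by the softmax), so gradient tests use an absolute floor.

Training: SGD, momentum 0.9, lr 0.001, batch 32, cross-entropy, per-step
multiplicative decay `lr_t = lr_0 (1 − 10⁻⁷)^t` — the stated "decay 10⁻⁷"
does not fix per-step vs per-epoch vs weight decay; per-step multiplicative
is the mildest reading and is negligible at package scales. Initialisation
is He-uniform under a named seed; epoch shuffling under another. Identical
seeds give bit-identical traces.

## Clump of features

Descriptors are the per-spatial-position channel vectors of the final conv
map, i.e. the exact reshape of the SFV into `(side/2)² × c3`; bag-of-features
needs local descriptors and this is the only locality the SFV natively
carries. The vocabulary is Lloyd's k-means with k-means++ seeding,
`max_iter 300`, relative-SSE tolerance 1e-4, emptied clusters re-seeded on
the worst-fit point; the per-iteration SSE trace is recorded and is
non-increasing by construction (asserted in tests, and the final SSE is
cross-checked against scikit-learn's k-means on separable instances).
Training descriptors are capped at a seeded subsample of 100,000 for
tractability. `k="auto"` picks the knee of the SSE-vs-k curve — the point
of maximum perpendicular distance to the chord between the curve's
endpoints, ties toward smaller k, degenerate curves falling back to the
smallest k with a warning — and logs a silhouette validation
(`s_i = (b_i − a_i)/max(a_i, b_i)`, singletons scoring 0) on a ≤2,000-point
seeded subsample, since silhouette is O(n²). `k = 10` is the documented
choice of the original elbow analysis and available as an explicit setting,
as is 4096 (the alternative printed reduction size; the two published
numbers are mutually inconsistent, so neither is hard-coded as canonical).
Histograms assign each descriptor to its nearest centroid (Euclidean, ties
to the lowest index) and normalise to sum 1. The vocabulary is a pure
function of the training split and seed — the inter-patient discipline —
and tests assert bit-identical centroids under test-split perturbation.

## Classification and metrics

SVM via scikit-learn SVC (one-vs-one multiclass, the convention for kernel
SVMs), default rbf with C=1, gamma="scale" — the kernel comparison the
package exposes (`kernel_sweep`) never declared a winner, so the default is
the common first choice. kNN uses 5 Euclidean neighbours.

Metrics: accuracy = trace/total (percent); per-class one-vs-rest tallies
give SE = TP/(TP+FN), SP = TN/(TN+FP), and kappa in the 2×2 product form
`2(TP·TN − FP·FN)/((TP+FP)(FP+TN)+(TP+FN)(FN+TN))`, which is algebraically
the textbook (po−pe)/(1−pe) on a 2×2 table (property-tested on random
tallies). Multiclass values are macro averages over classes, with
undefined-denominator classes excluded under a warning — the single-number
convention used by the comparison tables this mirrors is unstated, and
macro averaging is the least class-imbalance-sensitive choice. The reported
F1 is the harmonic mean of SE and SP (that is this framework's stated
definition — note it is *not* the precision/recall F1), and
error = 100 − accuracy exactly. Display rounding: percentages to 2
decimals, F1/kappa to 3.

## Synthetic data

Beats are sums of Gaussian waves (P, Q, R, S, T: centre, width, amplitude)
plus a 0.3 Hz sinusoidal baseline and white Gaussian noise — McSharry-style
morphology without the ODE: analytic, seed-stable, and class-separable by
construction. `rate_jitter` shifts all wave centres by a common
N(0, jitter·duration) draw per beat, emulating rhythm irregularity. The
default roster names the 17 classes of the MIT-BIH-derived fragment
taxonomy with stylised morphological differences (ectopic humps, widened
QRS, missing P, sawtooth flutter) and reproduces its per-class imbalance
(283 NSR … 10 SDHB, 1000 beats). `well_separated_suite` builds n classes
with pairwise-distinct R amplitude (0.6 + 0.25i mV), QRS width
(12 + 14i ms), alternating P-wave presence and T polarity, noise sd
0.02 mV, baseline 0.04 mV — deliberately clean, intended to be separable
after the full pipeline.

What the generator does *not* emulate: inter-patient variability, electrode
noise spectra, arrhythmia dynamics across beats (each beat is independent),
multi-lead structure, or physiologically validated waveforms. Passing
end-to-end tests therefore demonstrates that the pipeline's machinery is
correct and that it separates classes whose scalograms differ — not
clinical-grade performance on real recordings, and the headline accuracies
published for the full-scale MIT-BIH experiment are out of scope here.

## Splitting

Stratified holdout, 70/30 by default; per-class test counts are
`round(0.3·n_c)` clamped so every class keeps at least one training member
(several classes in the default roster have only 10 beats; unstratified
splits can empty them). Ten-fold stratified CV is available behind
`cv_folds` — both split descriptions exist in the protocol being followed,
and holdout is the one stated unambiguously; under CV, classes with fewer
than 2 members stay in training for every fold with a warning. All
randomness flows from one root `seed` through named substreams (split,
init, shuffle, kmeans, clf); the persisted manifest records them, and a
rerun with the same config and seed is bit-identical.

## Problem sizes and numerical choices

Library defaults target the reference geometry; tests and the demo run a
scaled-down geometry chosen as the package's standard small configuration:
input 64, channels (8,16,32), 5 epochs, 4 classes × 50 beats — large enough
that the attention matrix (1024×1024 per sample) and the CoF stage are
exercised in earnest, small enough for interactive runs. The full-geometry
network is instantiated (allocation + counting) rather than trained
anywhere in the package. Tolerances: attention row sums to 1 within 1e-6;
RFV normalisation 1e-9; k-means SSE tolerance 1e-4 relative; CWT-vs-
quadrature 5 % relative L2; gradient checks 1e-7 absolute + 1e-5 relative.

## Known limitations

- The attention gate at full 256 resolution relies on key/value subsampling;
  the exact (subsample 1) computation at that size is memory-hungry.
- On the deliberately separable synthetic suite both the gated and the
  ablated pipeline can reach 100 % held-out accuracy, in which case their
  confusion matrices coincide; the ablation's effect is then observable
  only at the feature level (the SFVs differ), not in the end metrics.
- The F1 reported is the SE/SP harmonic mean, not comparable to
  precision/recall F1 values from other work.
- `load_wfdb` is an optional capability; without the `wfdb` package it
  raises a capability error and the core pipeline is unaffected.
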