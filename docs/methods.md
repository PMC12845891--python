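# Methods

## Problem and model

The package treats beat detection in single-lead ECG as per-sample
semantic segmentation over four classes: background (0), Normal (1),
PVC (2), PAC (3). Targets are painted around each annotated R-peak:
100 ms before to 100 ms after for Normal and PAC, 100 ms before to 150 ms
after for PVC (the wider ventricular complex). Offsets in samples are
`round(ms·fs/1000)` with ties rounded half up; all intervals are
half-open; when windows overlap, a sample takes the class of the nearest
R-peak, with exact ties resolved PVC > PAC > Normal — consistent with the
detection-side hierarchy.

The network is a fully convolutional 1D U-Net with a ConvNeXt V2 encoder
(stem k=4/s=4, three k=2/s=2 downsamplings, depthwise-k=7 blocks with
pointwise ×4 expansion, GELU, Global Response Normalization, residuals),
a two-layer depthwise-separable bottleneck, and a light decoder
(linear upsampling, skip concatenation, conv k=3, LayerNorm, LeakyReLU
slope 0.01). Because the encoder downsamples by 32 overall, inputs are
right-padded with zeros to the next multiple of 32 and the output cropped
back, preserving the exact L×C contract for arbitrary lengths. The
minimum input length is enforced as a contract constant of 400 samples
(3.2 s at 125 Hz). LayerNorm acts over channels at each time step,
following the ConvNeXt family.

Where the architecture leaves choices open they are fixed as: blocks per
stage default (2,2,2,2) (the small experiment model uses (1,1,1,1));
pointwise expansion ratio 4; skip fusion by channel concatenation;
linear-interpolation upsampling (×2 per block, ×4 in the last block to
undo the stem); decoder kernel 3.

The whole network, including training, runs on a purpose-built
reverse-mode autodiff engine over NumPy float32 arrays
(`ecgseg._autograd`). Its primitives (strided/grouped 1-D convolution,
channelwise LayerNorm, GELU, linear upsampling, reductions) are verified
against central finite differences in the test suite; note that
finite-difference checks through the *whole* network are unreliable in
float32 because LayerNorm curvature at the 0.02 weight scale dominates
any usable step size — the suite therefore checks primitives directly and
the full model functionally (loss descent, every parameter updated).

## Training

Soft Dice loss, unweighted macro average over all four classes including
background, with smoothing constant ε = 1 in numerator and denominator so
that empty classes contribute a perfect ratio (ε/ε = 1). Optimizer AdamW
(β₁ = 0.9, β₂ = 0.999, weight decay 0), learning rate 10⁻³ under a
one-cycle schedule (30% cosine warmup from lr/25, cosine decay to
lr/10⁴). Segments containing at least one PVC or PAC are oversampled
(default factor 4; a segment with both takes the larger factor). Early
stopping tracks the mean of the PVC and PAC F1 scores computed on the
validation records through the complete inference + post-processing +
matching path; the best checkpoint is restored. One master seed fans out
to parameter initialization, the sampler and the augmentation stream.

Augmentation (training only, each transform drawn independently per
segment): amplitude scaling p=0.75 in [0.6, 1.4]; offset p=0.75 in
[−0.1, 0.1] mV; Gaussian/pink/brown noise p=0.75 (spectrally shaped white
noise, RMS drawn from [0.01, 0.1] mV); baseline wander p=0.75 (1–3
sinusoids, 0.05–0.5 Hz, 0.05–0.3 mV); spikes p=0.25 (1–5 impulses, 1–3
samples, ±0.5–2 mV); crop-and-pad p=0.25 (crop a leading fraction
U(0.8, 1.0), stretch back, mask resampled nearest-neighbor — beats inside
the cropped-off tail are necessarily dropped, so beat-count conservation
holds for the retained span); inversion p=0.35. Signal masking, temporal
shifting, mixup and cutmix are deliberately excluded. Noise amplitude
ranges are package choices; only the probabilities and the scale/offset
ranges are externally prescribed.

## Post-processing and evaluation

QRS mask = 1 − background probability (rows are softmaxed). Maximal runs
above threshold 0.9 lasting at least 40 ms (the minimum duration is a
package choice, set below any plausible QRS width) become detections;
each region is labelled by the argmax of the per-region means of the
three beat-class columns, located at the region midpoint
`floor((start+end−1)/2)`, with confidence the winning mean. Multi-lead
merging clusters detections within 150 ms left-to-right and votes:
majority first, hierarchy PVC > PAC > Normal only for ties (a
`any_pvc_wins` switch makes the hierarchy absolute, since the ordering of
the two mechanisms is ambiguous in prose descriptions of such voting).

Matching is one-to-one greedy nearest-first with a configurable tolerance
half-width, default 75 ms (a "150 ms interval centered" on the
reference); references — and, symmetrically, predictions — in the first
or last 0.2 s of a record are excluded. With inter-beat spacing above
twice the tolerance the greedy matcher is provably optimal; the suite
cross-checks it against an assignment-problem oracle. Se = TP/(TP+FN),
Pr = TP/(TP+FP), F1 the harmonic mean; 0/0 is reported as absent rather
than zero. Pooling across records is micro (summed counts); per-record
counts feed a nonparametric bootstrap over records (default 1000
iterations) with bias-corrected and accelerated (BCa) 95% intervals via
`scipy.stats.bootstrap`, falling back to percentile intervals if the BCa
correction is degenerate, and reporting zero-width intervals when every
replicate coincides.

Note one property that a run-based extractor does *not* have: lowering
the QRS threshold can merge two regions and so reduce the region count;
what is monotone is the above-threshold support, and the tests assert
exactly that.

## Synthetic data

Beats are sums of Gaussians placed relative to the R-peak (P, Q, R, S, T;
amplitudes/offsets/widths in mV/ms), the standard analytically
controllable construction. PVCs widen the QRS Gaussians ×2, scale them
×1.3, drop the P-wave, invert the T-wave, couple prematurely
(`coupling_frac`, default 0.6 of the sinus RR) and are followed by a
compensatory pause (the RR pair around an isolated PVC spans two sinus
intervals). PACs keep the narrow-QRS morphology, couple prematurely, and
jitter the P-wave amplitude (U(0.5, 1.3)), so their cue is chiefly timing
plus the early P — mirroring how such beats differ clinically. Ectopic
beats can extend into runs of ≥3 (`run_prob`). White noise is scaled to a
target SNR (default 20 dB) and an optional baseline sinusoid added.

The generator emulates: morphology contrast between the three classes,
coupling-interval prematurity, compensatory pauses, runs/couplets, and
moderate noise. It does not emulate: inter-patient morphology variability,
electrode artifacts, atrial fibrillation/flutter, fusion or paced beats,
P-waves hidden in T-waves, or annotation noise. Passing the end-to-end
test therefore demonstrates that the architecture, loss, optimization and
post-processing are implemented coherently and can recover the generative
structure — not that the model reaches any particular performance on real
Holter data, where published detectors of this family report QRS F1 near
0.99 but PAC F1 nearer 0.7.

## Experiment scale

The shipped end-to-end experiment trains the small model (base 16
filters, one ConvNeXt block per stage, ≈287k parameters) on 400 synthetic
20-s records (~10% PVC, ~10% PAC beats, three heart-rate/SNR regimes),
early-stops against 30 validation records, and evaluates on 50 held-out
records — sizes chosen so the whole pipeline, on one CPU, trains in about
two minutes while still containing several hundred ectopic beats per
split. Typical results: QRS F1 ≈ 1.00, PVC F1 ≥ 0.99, PAC F1 ≥ 0.98, with
BCa CI widths of a few percent on the ectopic classes.

## Interpretability

`layer_gradcam` adapts Grad-CAM to segmentation output: the scalar target
is the time-summed logit of the chosen class (invariant to adding a
constant to all logits), channel gradients are time-averaged into weights,
the weighted activation sum is rectified and linearly upsampled to the
input length; the default attribution layer is the final decoder
convolution. Kernel diagnostics treat first-layer kernels as FIR filters
(magnitude/phase response, −3 dB cutoff) and report the Pearson
correlation matrix between flattened kernels — near-zero off-diagonal
correlations indicate the filters learned distinct patterns;
zero-variance kernels are reported as absent rather than zero.

## File formats

WFDB support is a minimal self-contained subset (text `.hea` headers,
format-16 int16 `.dat` signals, MIT-format `.atr` beat annotations with
SKIP escapes) sufficient for round-tripping records and beat lists; the
CSV dialect (`fs=<Hz>` header line, lead-name line, one row per sample;
beat lists as `sample_index,label,confidence` with N/V/S symbols) is
designed for readable fixtures. Annotation mnemonics map to classes as
Normal = {NORMAL, LBBB, RBBB, BBB}, PAC = {NPC, APC, SVPB, ABERR, NESC,
AESC, SVESC}, PVC = {RONT, PVC, VESC}; everything else is excluded from
scoring. Preprocessing applies a zero-phase order-2 Butterworth high-pass
at 0.5 Hz (forward–backward, effective order 4), a Q=30 powerline notch
(50 or 60 Hz), and linear-interpolation resampling to 125 Hz; amplitude
is deliberately not normalized. The Butterworth order and notch design
are package choices exposed in `PreprocessConfig`.

## Known limitations

* The autodiff engine is single-threaded NumPy; it is sized for desk-scale
  experiments, not for training on millions of segments.
* Only dilation 1 is implemented in the encoder blocks.
* The synthetic generator's limitations above bound what any green test
  here implies about clinical data.
* Checkpoints are `.npz` archives tied to a config hash; there is no
  cross-version migration.
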