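# Methods

`caprilung` implements an end-to-end pipeline for classifying goat lung
auscultation recordings into four classes — Normal (0), Rhonchi (1),
Tachypnea (2), Noise (3) — from mono 16-bit 8 kHz WAV files with
single-integer `.txt` label sidecars (ICBHI-style pairing). This note
records the model, the numerical choices, and what the synthetic data can
and cannot establish.

## Signal path

**Segmentation.** Recordings are cut into fixed-duration windows (default
10 s, 50% overlap; window k starts at `k·d·(1−overlap)`). Incomplete tail
windows are discarded rather than zero-padded: padding would distort
spectro-temporal statistics, and clinical practice reads 3–5 respiratory
cycles, which 10 s covers at caprine rates. A recording shorter than one
window yields no segments.

**Bandpass.** A fourth-order Butterworth bandpass, 50–2000 Hz at 8 kHz,
applied forward–backward (zero-phase) so breath-envelope timing is not
skewed. Zero-phase filtering doubles the effective order; the half-power
points of the single-pass response sit at the design cutoffs (checked to
±0.2 dB in the tests). Filters are realized as second-order sections for
numerical stability.

**Gammatonegram.** The auditory front-end is a bank of 64 gammatone
filters,

    g(t) = a · t^(n−1) · exp(−2π b ERB(fc) t) · cos(2π fc t + φ),

with order n = 4 and decay factor b = 1.019. For the equivalent rectangular
bandwidth we adopt the Glasberg–Moore form ERB(f) = 24.7·(4.37 f/1000 + 1),
the standard auditory-modelling choice. Centre frequencies are spaced
uniformly on the ERB-rate scale between 50 and 2000 Hz with the endpoints
pinned exactly. Each filter is realized as an FIR by truncating the impulse
response at 128 ms (`--ir-length` equivalent: the `ir_length_s` argument);
the envelope has decayed below −80 dB by then for every centre frequency in
band. FIR gains are normalized to unity at each filter's centre frequency,
which makes the tone-tracking property (a pure tone at centre k peaks in
row k) hold by construction. Filtering runs through one shared FFT of the
segment in single precision; the ~7 significant digits this keeps are far
below the dynamic range that survives log compression. Frame energies use
25 ms frames with 10 ms hop (a 10 s segment gives 998 frames), and cells
are `log10(1e−10 + mean energy)` — the floor keeps silence finite at
exactly −10.

**Model input.** The filters × frames matrix is resized bilinearly to a
square (224 for the full backbone; 96 in the reduced CPU configuration),
standardized per sample (variance floor: a constant image maps to zeros),
and replicated to 3 channels. Row order — ascending centre frequency — is
preserved through the resize; the frequency-aware MLP's band convention
depends on it and a test pins it.

**Class balancing.** SMOTE in feature space: each synthetic vector is
`x_i + u·(x_nn − x_i)`, u ~ U[0,1], with `x_nn` among the k = 5 nearest
same-class neighbours of `x_i`. Originals are never perturbed; every class
is raised to the majority count. Balancing operates on flattened
gammatonegram matrices — the model's input representation — not raw audio,
since waveform surgery can corrupt the time–frequency microstructure that
carries the pathology. In cross-validation, balancing is applied inside
each training fold after the split; whole-dataset balancing is also
available from the library for corpus-level bookkeeping.

## The classifier

The backbone is a four-stage hierarchical windowed-attention transformer
(tiny configuration: embed 96, depths 2-2-6-2, heads 3-6-12-24, window 7,
4×4 patch embedding, MLP ratio 4, pre-norm residual blocks, cyclic shift of
half a window on alternate blocks with the standard seam masks). This
configuration is not arbitrary: with a 4-class head it counts 27.52 M
trainable parameters and ≈4.5 G MACs at 224², matching the published
complexity of the method this package reconstructs. When a stage's token
grid is smaller than the window, the window clamps to the grid and the
shift is disabled. The classification head is a LayerNorm, global average
pool over tokens, and a linear map to 4 logits.

Three modules replace standard components, each behind a config flag:

**Axial decomposed attention (ADA, `use_ada`)** replaces window attention.
One shared linear projection produces Q, K, V. Within each 7×7 window the
temporal branch attends across time (per frequency row) and the frequency
branch across frequency (per time column), each with per-head scaling
1/√d_k and softmax normalization; the two branch outputs are concatenated
on channels and fused by a 2C→C linear layer. Design points the definition
leaves open, resolved here: Q_f = G(Q) by symmetry with the temporal
branch; d_k = C/heads; cyclic shift is retained (per-axis seam masks);
no relative-position bias inside ADA because the branch attention has no
bias term — the baseline window attention keeps its bias table. The
parameter-count consequence (per block: +C² from the wider fusion, −(2w−1)²·
heads from the dropped bias table) reproduces the published +2.16 M delta
exactly, which is the strongest available evidence for this reading.

**Adaptive spatial aggregation patch merging (ASAP, `use_asap`)** replaces
patch merging. A salience head — LayerNorm, depthwise 3×3, pointwise C→1,
sigmoid — scores each position; a steep sigmoid `σ(10·(salience − α))`
with learnable threshold α (init 0.5, slope fixed at 10) turns scores into
a soft mask; the *raw* (un-normalized) input is weighted by the mask,
average-pooled 2×2, and expanded C→2C by a 1×1 convolution. In the α → −∞
limit the mask saturates at 1 and the module provably reduces to
pool-then-expand (an acceptance check). Replacing the 4C→2C merging
projection with this head removes ≈1.16 M parameters over the three
transitions, again matching the published delta.

**Frequency-aware MLP (FAM, `use_fam`)** replaces the per-block MLP. The
token grid splits along frequency into bands of heights (⌊H/3⌋, ⌊H/3⌋,
H−2⌊H/3⌋). The slowly-varying low band gets a bottleneck C→C/2→C with
GELU; the mid band C→C→C with GELU; the detail-rich high band C→2C→C with
SiLU; bands are re-concatenated along frequency and fused by a C→C linear
layer. Note these capacities sum to 8C² weights per block — the same as
the MLP they replace (the C² fusion exactly offsets the narrower low
band) — so the published FAM-row parameter counts (≈74–75 M) are not
reproducible from the stated branch widths; this package follows the
stated widths and excludes those rows from its checks rather than
inflating capacities to chase the table.

**Complexity accounting.** Parameter counts are exact sums over trainable
arrays. The MAC estimator walks the architecture analytically, counting
matmul/conv work only (norms and activations ignored), the usual convention
of transformer FLOP counters; it is a diagnostic, accurate to the ~10%
level across counting conventions.

## Autodiff engine

The network, loss and Adam optimizer run on a small reverse-mode autodiff
engine over numpy arrays written for this package (`caprilung.nn`): a
tape-based `Tensor` with analytic vector–Jacobian products for dense
algebra, shape surgery, softmax, LayerNorm and the activations. Every op is
validated against central finite differences in the test suite, and the
assembled network passes end-to-end gradient checks on both the baseline
and the fully-flagged configuration. Gradient buffers are ownership-aware
(freshly allocated gradients are adopted, pass-through gradients copied) so
residual connections accumulate correctly without defensive copying
everywhere.

## Training and evaluation protocol

Training uses Adam with cross-entropy; the published protocol (lr 1e-4,
batch 32, 50 epochs, 5-fold cross-validation) is the default `TrainSpec`.
Folds are stratified by class; optional group ids keep all segments of one
source recording in a single fold — overlapping segments of one recording
are near-duplicates, and splitting them across folds would leak. Both modes
exist because the original protocol's split level is unstated; grouping is
the default in the pipeline. Best-epoch weights are selected by validation
accuracy when a validation split is provided. Runs are bit-reproducible
for a fixed seed (pure-numpy arithmetic, one seeded generator).

Metrics, with per-class totals Nl, W, T, Ne and correct counts on the
diagonal: Accuracy = total correct / total; Se = (W_w + T_t)/(W + T) over
the two abnormal classes; Sp = Nl_nl/Nl over Normal; Score = (Se + Sp)/2.
Noise contributes to Accuracy only. Zero denominators raise rather than
returning NaN. Printed values use half-up decimal rounding (after
quantizing float noise at 6 dp), matching how such tables are printed.

## Synthetic data: what it emulates and what it does not

The generator produces class-conditional caricatures of auscultation
acoustics: band-limited breath noise (50–800 Hz) under an
inspiration-dominant periodic envelope at 12–30 breaths/min (Normal); the
same plus a continuous amplitude-modulated low tone at 80–300 Hz with
tonal gain 1.5–3× the breath RMS (Rhonchi); the normal structure at 40–80
breaths/min (Tachypnea — kept disjoint from the normal range so labels are
unambiguous); and pink ambient noise with Poisson-timed 20–100 ms friction
transients, breath content attenuated 14 dB (Noise). Breath-vs-ambient SNR
is drawn in 10–20 dB. All randomness flows from one seed through spawned
per-recording seeds, so manifests are reproducible regardless of
generation order.

These defaults encode the qualitative class structure the real task is
defined by — rate, tonality, noise dominance, low-frequency energy
concentration — and nothing subtler: no goat physiology, no auscultation
site variation, no inter-animal heterogeneity, and far cleaner class
boundaries than field recordings. Consequently the end-to-end checks
(a reduced model exceeding 60% four-class accuracy on held-out synthetic
data, against 25% chance) verify that the pipeline wiring and the
architecture can extract the intended structure; they say nothing about
accuracy on real goats, and the published real-data figures are not
reproduction targets here because that dataset is not public.

## Problem sizes for the automated checks

The desk-scale checks build the full 224² backbone (parameter counting
needs no forward pass). The training checks use the reduced configuration
(embed 24, depths 1-1-1-1, heads 2-4-8-16, 96² input, window 6 — chosen so
every stage grid divides its window and the last-stage height 3 still
admits the three-band split), 200 synthetic samples per class for training
and 40 per class held out, 6 epochs at lr 1e-3, and a 32-sample overfit
probe capped at 200 steps. These sizes were chosen as the smallest at which
the properties under test are clearly expressed.

## Known limitations

- The engine is CPU-bound, single-threaded numpy; full-scale 224² training
  is possible but slow, and the package makes no attempt at GPU execution.
- FIR truncation at 128 ms slightly widens the effective filter skirts for
  the lowest centre frequencies relative to an IIR gammatone realization.
- The MAC estimator ignores normalization/activation work by convention.
- Stage grids must be divisible by the (clamped) window; arbitrary input
  sizes would need the pad-and-mask scheme, which is not implemented.
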