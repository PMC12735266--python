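# Methods

This note records the model implemented by `lfe`, the choices made where the
method leaves room, and what the packaged synthetic experiments do and do not
demonstrate.

## Model and training procedure

**Count-map representation.** Object centers are represented as unit impulses
in a location map; supervision happens on the r×r box sum (redundant count
map).  Windows are clipped at the image border — equivalently the box sum is a
zero-padded convolution — which preserves non-negativity and conserves the mass
of interior objects exactly (`sum(C) = r²·n` when all objects are at least
⌈r/2⌉ px from the border).  The operator is linear and self-adjoint, which the
trainer uses to backpropagate count-map losses through to the predictor.
Coordinates are 0-based `(row, col)`; fractional annotations rasterize to the
nearest pixel with ties toward the smaller index.

**PU risk (stage 1).** Known positives are the non-zero entries of the
partially annotated count map; everything else is unlabeled, and the entire
training set serves as the unlabeled pool (the risk does not require
independence of the two).  The positive term is the mean squared count error
over masked entries (1/N_p normalization); the negative term is the mean
`tanh` of predicted counts over all N entries of the batch minus `π_p/N_p`
times its masked sum; the negative term is clamped at zero.  The clamp
backpropagates a zero subgradient when active — the plain `max` reading; no
gradient-ascent correction step is used.  `N` counts every count-map entry of
every image in the batch (positive and unlabeled alike), `N_p` every masked
entry in the batch.

**Batches and schedule.** A batch holds `4n` images: `n` annotated images,
`n` rotated/flipped copies of them (annotations transformed consistently), and
`2n` draws from the unlabeled pool.  Each epoch a fresh random ⌈2/3·k⌉ of each
image's k annotations is used.  Adam optimizes stage 1 at 1e-4 (the reference
rate for batches of ≥ 8; smaller batches scale the rate down linearly) and
stage 2 at 1e-6.  Validation F1 is computed only after a 20-epoch delay —
early maps are noise and peak search on them is wasted work — and the best
validation checkpoint of each stage is kept.  When validation F1 plateaus for
10 consecutive evaluations the learning rate is halved.  Model selection
assumes fully annotated validation images; with sparse validation labels the
selected checkpoint would be biased toward recall on the labeled subset.

**Pseudo-labeling (stage 2).** Once per epoch the unlabeled losses
`l = C_pre²` of all training images are pooled, clear negatives (`l < 0.01`,
applied on the raw scale) are removed, the survivors are mapped affinely onto
(ε, 1−ε) with ε = 1e-4 (beta support; the bounds are stored so posteriors can
be queried for any raw loss), and a two-component beta mixture is fitted by
EM.  The E-step is standard; the M-step re-estimates the weights as mean
responsibilities and the beta shapes by *weighted maximum likelihood* (L-BFGS
on the digamma equations, initialized from weighted moments).  An exact M-step
makes the observed-data log-likelihood provably non-decreasing; a plain
moments update does not, and measurably violates monotonicity on bimodal
samples.  Initialization splits the sample at the median, so the fit is
deterministic given the data; the seed only feeds a random re-initialization
used if a component collapses (< 2 effective points).

Local maxima of each predicted map are scored by the posterior of the
high-mean ("noisy", i.e. hidden-object) component.  Peaks with posterior
≥ τ⁺ = 0.95 become predicted positives, ≤ τ⁻ = 0.05 (and all unlabeled
non-peak coordinates with surviving losses) predicted negatives, and the band
in between is ignored — injecting a false positive is costlier than skipping a
true one.  Both thresholds are configuration options.  Provided labels always
win: a peak on (or within ⌈r/2⌉ Chebyshev of) a provided positive is absorbed
rather than double-counted.  The refinement loss is
`(1/N)[Σ_{Φ⁺}(C_pre−1)² + Σ_{Φ⁻} tanh(C_pre)]`; the unit target reflects that
a kernel smaller than the objects covers at most one object per positive
window.  Stage 2 partitions against the full provided annotation set (the 2/3
resampling is a stage-1 stabilizer; with one label per image the two choices
coincide).

**Predictor.** Any encoder–decoder producing a same-resolution non-negative
map fits the contract.  The packaged one is a small U-style NumPy network
(two resolution levels, 8 base channels, ~5k parameters): conv 3×3 → batch
norm → leaky ReLU blocks, 2×2 average pooling, nearest upsampling with skip
concatenation, and a 1×1 head.  Two numerical choices matter and were made
deliberately:

* *Batch normalization is load-bearing.*  Until the network can tell objects
  from background, the PU risk exerts a net downward force on the whole map
  (the `tanh` term sums over ~N entries against a positive pull of weight
  π_p); without normalization the shared output bias sinks every
  pre-activation below zero first and training freezes permanently at the
  all-zero map with risk π_p.  Normalized features keep object/background
  contrast at unit scale so the head can separate them while the background
  sinks.
* *The output nonlinearity is a sharp scaled softplus*, `log(1+e^{βz})/β`
  with β = 10: non-negative and ReLU-like away from zero, but with a strictly
  positive gradient so no pixel is permanently trapped at zero.  A hard ReLU
  output (`out_activation="relu"`) is available and equivalent at inference,
  but can die irrecoverably during stage-1 training at these scales.
* *The head starts the map low* (bias −0.2 through the softplus gives initial
  responses ≈ 0.01, initial counts ≈ 0.6).  Starting with counts of several
  units saturates the `tanh` background loss (gradient `sech²` of the counts
  ≈ 0.002) and stretches early stage-1 training into a long flat creep; with
  counts below 1 the background term is responsive from the first step and
  convergence on the packaged benchmark shortens from ~80 to ~12 epochs.

Gradients of every layer are exact and checked against finite differences in
the test suite.  Inputs of arbitrary size are edge-padded to the pooling
multiple and cropped back.

**Localization and metrics.** Detections are local maxima over r×r Chebyshev
neighborhoods (matching the square kernel geometry), at least 10% of the map
maximum (a scale-free floor above the activation noise floor), with plateau
ties resolved to the lexicographically smallest coordinate and no two peaks
within ⌊r/2⌋ Chebyshev.  Peak prominence is reported as the peak value and its
share of the surrounding r×r window sum (the only normalization that keeps the
share ≤ 1), against the analytic baseline `1/(2πσ²)`, σ = r/6 — the central
density a matched Gaussian kernel would place at a center.  Matching is greedy
nearest-first one-to-one with distances strictly below the threshold
(6 px for histopathology-scale data, the minimal object radius otherwise);
a Hungarian variant is available for sensitivity checks.  Greedy matching is
maximal but not always maximum-cardinality: on random ≤3×3 instances it loses
a pair in ~2% of cases, which the test suite documents via the provable bound
`optimal − 1 ≤ greedy ≤ optimal`.  The mean localization error averages
matched distances; unmatched points on either side contribute a configurable
penalty (default: the matching threshold), since the reference protocol for
that penalty is not fully specified.

## Synthetic data and the packaged benchmark

The generator renders quasi-circular bright objects on a darker background:
soft-edged disks (1-px anti-aliased rim) with a gentle 10% center-to-rim dome
so the intensity maximum sits at the recorded center, packed by rejection
sampling with a minimum separation and a border margin, plus additive Gaussian
noise, clipped to [0,1].  Defaults define the packaged benchmark: 96×96 px,
15 disks of radius 4 (diameter 9, just above the 7-px kernel), contrast 0.6
over background 0.15, noise σ = 0.03, one labeled point per image, minimum
separation 11 px.  All draws derive from named substreams of one master seed;
generation is bit-reproducible.

The benchmark trains on 48 images (≈7% of annotations labeled), selects on 8
fully annotated validation images, and tests on 16, with greedy matching at
4 px (the object radius).  The schedule is scaled to this task's convergence
— 50 PU epochs (delay 20) and 15 refinement epochs; the full-scale defaults
remain 100 + 100 — and a further shrunken variant (64×64, 8 objects, 24
training images, 30 + 10 epochs) backs the multi-seed stage-2 regression
property in the test suite.

What passing these tests shows: the full pipeline — count maps, PU risk,
mixture pseudo-labeling, peak readout, matching — is implemented consistently
and learns to localize from a single annotation per image under realistic
class-prior mismatch (true prior ≈ 0.08 vs. the fixed 0.1).  What it does not
show: performance on real stained tissue, droplets, or crowds (texture,
illumination gradients, perspective scaling, object shape variability, and
annotation jitter are all absent), nor the scalability of the NumPy predictor
beyond desk-scale images.

## Degenerate inputs and tie-breaks

* No positive entries in a batch (`N_p = 0`): the positive risk raises and the
  batch is skipped; the negative risk defines its correction term as 0.
* No surviving unlabeled losses, or fewer than 10: pseudo-labeling is skipped
  for that epoch with a warning.
* Empty positive pseudo-label set for an image: its update is skipped (a PN
  stage with no positives collapses to the zero map).
* A validation epoch with no detections scores precision 1 only when there is
  also no ground truth; the F1 conventions for empty denominators are fixed
  in `evaluate.detection_scores`.
* EM component collapse triggers one random re-initialization, then a hard
  error.

## Known limitations

* The clipped box window under-penalizes image corners (a corner count map
  entry aggregates ~r²/4 windows instead of r²), so weakly trained models can
  show spurious corner responses just above the peak floor; converged models
  do not.
* The NumPy predictor is single-threaded and desk-scale; swapping in any
  same-resolution encoder–decoder (e.g. a GPU implementation) only requires
  honoring the non-negative-output contract.
* The class prior is treated as known (0.1 across experiments, as in the
  reference protocol); a grossly wrong prior shifts the de-biasing term and
  degrades stage-1 equilibria.
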