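# Methods

This note documents the models, conventions and design choices behind the
package, what the synthetic phantoms do and do not emulate, and the
problem sizes used in the reference experiments.

## Pipeline overview

The package processes apical four-chamber echocardiogram frames in three
stages:

1. **Cone masking** (`echoseg.cone`): the pie-slice scan sector is
   isolated so screen-capture overlays (text, ECG trace) cannot confuse
   the segmenter. The module refines an externally supplied detector mask
   (smoothing + dilation) or extracts one geometrically.
2. **Four-chamber segmentation** (`echoseg.unet`, `echoseg.train`): a
   compact U-Net assigns each pixel one of five classes — background,
   left ventricle (1), left atrium (2), right ventricle (3), right
   atrium (4).
3. **Heuristic correction** (`echoseg.correct`): anatomically impossible
   vertical overlaps between a ventricle mask and its same-side atrium
   mask are detected and clipped; masks can additionally be eroded
   uniformly for display.

Coordinates are 0-based with the row index *y* increasing downward; a
pixel coordinate is written (x = column, y = row). Label maps are
exchanged as integer images valued in {0..4} and serialized as indexed
PNGs (palette position = class id).

## Segmentation network

The network is the classic encoder–decoder with skip concatenations at
reduced width: contraction channels 16/32/64/128 (two 3×3 same-padded
convolutions per block, each followed by a rectifier and then batch
normalization, then 2×2 max-pooling), a 256-channel bottleneck, and a
mirrored expansion path using 2×2 stride-2 transposed convolutions with
bias and no normalization. Upsampled feature maps are concatenated with
the same-scale contraction output (e.g. 256 + 128 = 384 channels at
16×16). The head is a 3×3 convolution to 8 channels followed by a 1×1
classification convolution to 5 channels; both head operations also carry
the rectifier + batch-norm pair. A 128×128×1 input reaches 8×8 at the
bottleneck and returns to 128×128×5 raw class scores; the label map is
the per-pixel argmax with ties resolved to the lowest class index.

Two deliberate readings are worth flagging:

* **Operation order is convolution → ReLU → batch norm**, including after
  the final 1×1 classification convolution. Normalizing rectified class
  scores before a softmax loss is unusual, but it is the configuration
  the audit certifies, so inference applies it too. The desk-scale
  experiments confirm it trains to high phantom Dice regardless.
* **The class count (5) and the transposed-convolution shape (2×2,
  stride 2, with bias, no batch norm) are pinned by parameter
  accounting**: the final-operation count 55 = 8·5 + 5 + 2·5 forces five
  classes, and 262,400 = 4·256·256 + 256 only fits a biased 2×2 kernel.
  Per-operation closed forms: 3×3 conv + BN = 9·c_in·c_out + 3·c_out;
  1×1 conv + BN = c_in·c_out + 3·c_out; 2×2 transposed conv =
  4·c_in·c_out + c_out. Grand total: 2,315,135 trainable parameters.

`audit_parameters` measures counts from the instantiated weight arrays
(not formulas) and the CLI (`echoseg unet audit`) diffs them against the
embedded reference table.

### Numerical implementation

The layer library (`echoseg.nn`) is a small NHWC float32 stack with
manual backpropagation, designed so a full desk-scale training run fits
in minutes of single-core CPU time. Convolutions use a
shift-and-accumulate scheme: the zero-padded activation tensor is viewed
as one long (pixels × channels) matrix and each kernel tap contributes
one BLAS GEMM accumulated in place at the tap's flat offset; interior
output pixels only ever read true neighbours (row crossings land in the
zero padding, batch crossings in cropped border rows), so the scheme is
exact with no im2col copy. Gradients are verified against central finite
differences in the test suite (float64, tolerance ~1e-4 relative).
Max-pool backward splits the gradient equally among exact within-window
ties, a valid subgradient that matches symmetric finite differences.
Weights use the fan-in-scaled uniform initialization
U(−1/√fan_in, 1/√fan_in) for weights and biases, seeded; batch norm uses
eps 1e-5 and running-statistics momentum 0.1.

## Training protocol

Frames are resized to 128×128 (bilinear) and normalized to [0, 1]; label
maps are resized with nearest-neighbour interpolation — the only
label-safe choice. The dataset is split 80/10/10 (validation and test
take floor allocations, the remainder trains); optimization is Adam
(β = 0.9/0.999, ε = 1e-8) at a fixed learning rate of 1e-3, per-pixel
unweighted multiclass cross-entropy, mini-batches of eight with
reshuffling each epoch, 50 epochs, final-epoch weights kept. One integer
seed fans out to the split, the shuffles and the initialization.
Validation and test metrics (macro Dice, macro IoU over the four chamber
classes, and mean pixel accuracy over the classes present in the
reference) are computed per image and then averaged (macro over frames);
per-class pixel accuracy is class recall.

**Reference problem size.** The desk-scale reference experiment trains on
200 synthetic 112×112 phantoms (160/20/20 after the split) for the full
50 epochs. On phantoms this configuration reaches held-out macro Dice
well above 0.95; the acceptance threshold is 0.85. These numbers
characterize the pipeline on synthetic data only — clinical frames are
far harder, and performance there is not implied.

## Heuristic correction

Each predicted class is first reduced to its largest connected component
(the predictor occasionally emits extra blobs). Per side, an overlap is
flagged when the ventricle's bottom row strictly exceeds the atrium's top
row. The severity measure is the Euclidean distance between the side's
two most extreme points — the ventricle's topmost pixel and the atrium's
bottommost pixel (one extreme per mask; ties within a row resolve to the
smallest column). If an overlap is flagged and the distance exceeds the
side threshold — 68.5 px for the right chambers, 76.5 px for the left, in
128×128-frame pixels, rescaled proportionally to the frame diagonal at
other resolutions — every ventricle pixel at rows ≥ the atrium's top row
is removed. Smaller overlaps are treated as regular anatomical contact
and ignored. A cut that would erase the whole ventricle signals a
pathological prediction; `correct_labelmap` records it per side instead
of failing the frame. The alternative reading of "most extreme points"
(ventricle bottom vs atrium top) was rejected: it would measure only the
overlap depth, which the overlap flag already captures, and it cannot
reproduce the documented example distance of 71.6 px.

Consequences used by the tests: the correction is idempotent (after a
cut the overlap test is false by construction), never adds pixels to any
chamber, and leaves the untouched side bit-identical.

Display erosion applies the same 3×3 rectangular element (1 iteration by
default) to every chamber. For congruent shapes this preserves area
ratios exactly; for general shapes the preservation is approximate and
is not asserted.

## Synthetic phantoms

`echoseg.phantom` generates the data regime the pipeline assumes, with
ground truth: a scan sector with apex at top-center, half-angle 45° and
depth 0.95·H; four elliptical cavities (intensity 0.12–0.25) in brighter
tissue (0.55), ventricles above their same-side atria, left chambers on
the image right as in clinical display; two constant-intensity burn-in
strips above the apex outside the sector; and multiplicative speckle.

Choices that were genuinely open:

* **Speckle model**: Rayleigh-distributed multiplicative noise smoothed
  with a σ = 1 px Gaussian to introduce spatial correlation, normalized
  to unit mean and blended at `speckle_scale` = 0.35 — a standard
  first-order B-mode approximation. Scale 0 reproduces the exact
  piecewise-constant image.
* **Sector half-angle 45°** (a clinical apical sector is ~90° total).
  This is load-bearing: the correction thresholds are absolute pixel
  distances, so chambers must span a realistic fraction of the frame —
  under a much narrower sector the ventricle-top-to-atrium-bottom span
  could never exceed the thresholds and no cut could ever fire, which
  would contradict how the corrector demonstrably behaves on clinical
  frames.
* **Placement**: base geometry is jittered per seed (centers ±2 px
  columns / ±1 px rows, semi-axes ±1 px, rotation up to ±8°) and invalid
  draws are retried with shrinking jitter; a configuration that cannot be
  placed raises an error naming the violated constraint.
* **Leak defects** (`inject_leak`): a connected band (~6 px wide)
  starting at the chamber's facing extreme row, advancing ~1 row per
  step while drifting outward ~0.7 px per row so it routes around the
  neighbour chamber, overwriting background only — reproducing the
  "ventricle wrapping the atrium" failure mode the corrector targets.

What the phantoms deliberately do **not** emulate: wall/valve texture,
Doppler overlays, temporal dynamics, probe-dependent attenuation, or
inter-observer annotation variability. Passing tests therefore show the
pipeline's mechanics (geometry handling, training dynamics, correction
logic) are sound, not that clinical-grade accuracy is achieved.

## Cone refinement choices

Smoothing: keep the largest component, then morphological closing and
opening with a 5-px-diameter disk, then hole filling — the standard way
to low-pass a mask boundary; it is a near-fixed-point on already-smooth
sectors. Dilation: 3×3 rectangular element, default 2 iterations
(exposed on the CLI). The geometric extractor thresholds with Otsu's
method (deterministic, parameter-free), keeps the largest component and
returns its filled convex hull — exact for convex sectors, which every
sector with half-angle ≤ 90° is.

## Known limitations

* The corrector only addresses vertical ventricle/atrium overlap on a
  side; left–right chamber swaps and temporal inconsistencies are out of
  scope.
* Thresholds (68.5/76.5) are fixed constants, not learned; their
  diagonal rescaling across resolutions is a package convention.
* The layer library implements exactly the operations this network
  needs (stride-1 same convolutions, 2×2 pooling and upsampling); it is
  not a general-purpose framework.
* Phantom realism is intentionally minimal (see above); reported phantom
  metrics must not be read as clinical performance.
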