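# Methods

## Problem setting

A cryo-ET acquisition session fixes microscope parameters, sample content and
preparation; micrographs from one session are therefore treated as draws from
one domain. Crystalline (non-vitrified) ice appears as bright, high-frequency,
strongly oriented texture; the cellular background is smooth and
low-frequency; contamination blobs and FIB-damage bubbles are high-contrast
distractors that must *not* be labeled as ice. The package frames per-dataset
adaptation as few-shot learning: a task τ bundles micrographs from one
dataset, split into a support set (1–10 labeled images, used for adaptation)
and a query set (used for evaluation only).

## Segmentation model

FPN with a configurable encoder, all group-norm:

* stem: 3×3 conv at full resolution;
* encoder stages (default channels 8/16/32): stride-2 3×3 conv, then either
  one residual block per stage (y = ReLU(F(x) + x), F = conv→GN→ReLU→conv→GN,
  post-addition ReLU) or a dense block (layer ℓ consumes the concatenation of
  the stage input and all previous layer outputs, followed by a 1×1
  transition back to the declared stage width);
* decoder: 1×1 lateral projections to a common width (default 8), top-down
  nearest ×2 upsampling with summation, a 3×3 + 1×1 head at the finest
  pyramid level, then a final ×2 upsample to full resolution. One sigmoid
  logit per pixel.

Group-norm replaces batch-norm because adaptation batches hold 1–10 images —
batch statistics would be degenerate exactly where the method must work.
Input sides must divide 2³; the inference path reflect-pads and crops.
Initialization is He-style for convolutions, identity for norms, zero biases,
reproducible from a seed. The default configuration has 32,001 parameters —
deliberately small so the full bi-level optimization runs on one CPU core.

## Differentiation

No pre-built autodiff framework is used: `cryoice.autodiff` is a reverse-mode
tape over numpy arrays in which every primitive's vector-Jacobian product is
itself composed of primitives. Calling `grad(..., create_graph=True)`
therefore returns gradients that can be differentiated again, which is what
the exact MAML meta-gradient requires. Convolution gradients are phrased as
convolutions of dilated/padded operands (with kernel flips and axis swaps),
so double backward through conv layers needs no special casing; the raw
convolution loops over whichever of kernel/output positions is smaller,
bounding memory by the output size. Correctness is pinned by
finite-difference tests, including Hessian-vector products through
convolution.

## Losses

`bce_plus_dice` (default): mean per-pixel binary cross-entropy with logits
(overflow-safe softplus form) plus soft Dice loss
1 − (2·|σ(l)·y| + ε)/(|σ(l)| + |y| + ε) with ε = 1. Foreground fractions in
realistic data sit at a few percent, where plain BCE underweights the
positive class; the Dice term compensates. Plain `bce` and `dice` are
selectable.

## Training strategies

* **Regular gradient descent** (`train_supervised`): full-batch by default so
  its trajectory provably coincides with the inner loop's under equal data,
  learning rate and step count (tested bitwise); optional deterministic
  mini-batching. Serves as both the pre-training path and the vanilla
  transfer baseline.
* **MAML** (`inner_adapt` / `meta_step` / `meta_train`): the inner loop runs
  `inner_steps` full-batch gradient steps at `inner_lr` on the support set;
  the outer loop applies plain SGD at `outer_lr` to the mean post-adaptation
  query loss over a batch of `meta_batch_tasks` tasks. `second_order=True`
  keeps the inner updates on the tape (exact meta-gradient);
  `second_order=False` (FOMAML, the default) detaches the inner gradients but
  keeps the identity path dφ/dθ = I. FOMAML is the practical choice at FPN
  scale — exact second order costs roughly 50× more per step here — while
  second-order correctness is verified exactly on small models.
* **k-shot fine-tuning** (`finetune_kshot`): gradient descent from a
  pre-trained initialization on k ∈ [1, 10] labeled pairs, with held-out IoU
  evaluated after every epoch and the best snapshot returned; ties break
  toward the earlier (less overfit) epoch. An empty held-out set falls back
  to the final epoch with a warning.

Default hyperparameters: `inner_lr` 0.01, `inner_steps` 5, `outer_lr` 1e-3,
meta-batch 4 tasks. All loops are pure functions of (inputs, config, seed);
determinism is tested at the byte level through the CLI.

## Synthetic data generator

A `SyntheticDatasetConfig` fixes one dataset's rendering parameters:
image size, background smoothness (Gaussian-filter sigma, px), i.i.d. noise
sd, target ice fraction, per-phase texture parameters (carrier frequency in
cycles/px below Nyquist, orientation, contrast, patch scale), and artifact
rate. Rendering one micrograph:

1. background = unit-variance Gaussian-smoothed noise field × 0.15 around a
   0.5 mean;
2. crystalline patches: rotated ellipses placed by rejection until the mask
   fraction lands in [0.5, 2.0] × target (an aim drawn per image keeps class
   imbalance realistic — affected lamellae typically show a few percent
   crystalline area);
   each patch is filled with oriented sinusoidal carriers — 1 for cubic, 3 at
   60° spacing for hexagonal, a random mixture of 2–3 orientations for
   stacking-disordered — at amplitude 0.30 × contrast. The amplitude is sized
   so that at contrast ≥ 1 the local gradient energy inside the mask exceeds
   the background's at least twofold: tasks are learnable by construction;
3. artifacts (dark discs, bright-rimmed bubbles) are placed so they overlap
   the positive mask by at most 10% of their own area and are never added to
   the labels;
4. pixel noise is added last.

Task families: `ConfigPrior` holds per-field uniform intervals; datasets
(tasks) are i.i.d. draws. Disjoint priors produce a measurable domain shift
(pooled-histogram KS statistic above the same-dataset baseline in ≥ 90% of
trials under the shifted priors exercised in the tests). Micrographs within a
task carry distinct lamella/series/tilt identifiers, mirroring the real
acquisition hierarchy purely as metadata.

What the generator does **not** emulate: contrast transfer function, dose and
tilt geometry, 3-D consistency across a tilt series, diffraction physics of
the ice phases, and real annotation noise. Passing tests therefore
demonstrate the algorithmic machinery (adaptation helps under domain shift
when tasks share exploitable structure), not field performance on microscope
data.

## I/O conventions

* MRC 2014 image stacks: little-endian, modes 0/1/2/6, `ispg = 0` required
  (volumes rejected); pixel size from cell dimensions / grid size. The
  writer is fixture-grade (no extended header).
* Multi-page TIFF via `tifffile`.
* CVAT-for-images XML: polygons as `points="x1,y1;…"`; CVAT (x, y) maps to
  image (col, row), 0-based. All labels are treated as crystalline ice unless
  filtered. Malformed or <3-vertex polygons raise with the offending image
  named.
* Rasterization: a pixel is foreground iff its integer-grid center lies
  inside (even-odd rule) or on the boundary of any polygon; boundary counts
  as inside for determinism and orientation independence. Vertices are
  clipped to the half-pixel border.
* Preprocessing: z-score, clip at ±3σ (cryo-ET exports carry hot pixels),
  affine rescale to [0, 1], bilinear resize to a target long side (default
  1024) preserving aspect; constant images map to uniform 0.5 with a logged
  warning rather than an error.

## Metrics and reporting

IoU and F1 with the both-empty convention = 1.0 (a clean lamella predicted
clean is a success); F1 = 2·IoU/(1+IoU) holds exactly for binary masks and is
property-tested. Percent non-vitrified = 100 × foreground/total pixels.
Dataset aggregation: mean ± z₀.₉₇₅·s/√n over per-image percentages (normal
approximation; micrographs, not pixels, are the unit of replication — pixels
within a micrograph are heavily correlated). The CI method is recorded in the
report metadata. k-shot curves use nested supports (the k-shot support is a
prefix of the (k+1)-shot support) so points are comparable along k.

## Problem sizes

The rapid-adaptation experiment in the tests and in `scripts/acceptance.py`
uses the default 32k-parameter FPN on 64×64 images, 120 first-order
meta-iterations (inner_lr = outer_lr = 0.05, 3 inner steps, 4 tasks/batch),
20 held-out tasks with 5-shot adaptation, and a 3-point k-shot curve — sizes
chosen so the whole run finishes in a few minutes on a single CPU core while
leaving a wide margin between the meta-trained and random initializations.

## Known limitations

* The synthetic prior stands in for a real pre-training corpus; absolute IoU
  values on synthetic tasks do not transfer to microscope data.
* Exact second-order MAML at FPN scale is supported but slow (pure-numpy
  double backward); FOMAML is the intended default beyond toy scale.
* The MRC reader covers image stacks only — tomogram volumes are explicitly
  rejected rather than sliced.
* No statistical comparison between methods is performed; curves report
  means only.
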