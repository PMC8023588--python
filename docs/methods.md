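# Methods

`octselect` studies a practical question in intravascular OCT (IVOCT)
segmentation: when an expert has outlined volumes of interest (VOIs) in a
pullback but can only annotate a fraction of their frames, **which frames
should be annotated** so that a 2D segmentation network trained on them
loses as little accuracy as possible? The package implements and compares
two samplers — equal z-spacing and deep-feature clustering — around a full
train/evaluate protocol, with a synthetic phantom generator standing in for
clinical data.

## Pipeline

### Preprocessing (polar domain)

Raw frames live in the polar (r, θ) acquisition geometry: rows are radial
depth, columns are A-lines. Per frame:

1. **Guidewire zeroing.** A-lines inside the guidewire shadow carry no
   tissue signal and are set to zero. When ground-truth shadow indices are
   not provided, a detector flags A-lines whose summed intensity beyond the
   lumen falls below `min(median − c·MAD, 0.05·median)` of the per-A-line
   sums and returns the widest circularly contiguous run. The relative
   floor is deliberate: a guidewire shadow is essentially zero-signal
   whereas a calcific lesion is attenuated but not extinguished, so a pure
   median−MAD rule can swallow a wide lesion arc into the "dark" set; the
   floor keeps it out. The detector is swappable and bypassed whenever the
   shadow annotation exists.
2. **Pixel-shift alignment.** Each A-line is shifted radially by its lumen
   offset so the lumen boundary sits at row 0. Shifts are integer (masks
   stay binary), vacated deep pixels are zero-filled, and the per-A-line
   shift is recorded so the operation inverts exactly on the retained
   depth.
3. **Crop, log, smooth.** The first 200 pixels (~1 mm at 5 µm/px) from the
   lumen are kept; intensities are mapped through `log(x + 1e-6)`,
   min–max rescaled to [0, 1] per frame (networks need bounded input; the
   rescale is this package's choice of normalization), then filtered with a
   7×7 Gaussian, σ = 1. Masks undergo the same integer geometry but are
   never filtered. Guidewire columns are re-zeroed after filtering so the
   all-zero contract survives kernel bleed.

### Frame selection

Both samplers choose `max(1, ceil(n·ratio))` frames per VOI.

* **Equal spacing** takes index `floor(j/ratio)` for `j = 0..m−1`. For the
  unit fractions used throughout (1/2, 1/3, 1/10) this is exactly the
  "every s-th frame" rule starting at 0; the floor formulation extends it
  to any rational ratio while keeping the selected count exactly
  `ceil(n·ratio)` (a plain stride of `round(1/ratio)` does not).
* **Clustering** trains a convolutional autoencoder on all frames of the
  VOI (MSE reconstruction, Adam, 100 epochs, lr 0.001, batch 64 by
  default), takes the global average of each bottleneck channel as the
  frame's feature vector, reduces with PCA to the fewest components
  explaining ≥ 95% of variance (fit per VOI, no whitening), and runs
  k-medoids (PAM: greedy BUILD, steepest improving SWAP to convergence,
  ties to the lowest index; SWAP restarts from a farthest-first and two
  seeded random initializations, keeping the lowest-cost solution, which
  removes the occasional shallow local minimum of single-start PAM) with k
  equal to the target count. The medoid
  frames — the most mutually dissimilar representatives — are selected.
  When k ≥ n all frames are returned without clustering.

Global average pooling (rather than flattening) of the bottleneck maps was
chosen so the feature dimension is independent of frame size and small
enough for a per-VOI PCA on a few dozen frames; flattening remains
available via configuration. The autoencoder deliberately has **no skip
connections** — with skips the bottleneck could be bypassed and its
features would carry little information about the frame.

### Networks

Both networks are compact numpy implementations (im2col convolutions,
hand-derived backprop, Adam) built for single-CPU training:

* **Autoencoder**: four stride-2 3×3 conv+ReLU stages (8→16→24→32
  channels), a 3×3 bottleneck at 1/16 resolution (32 channels — kept a few
  dozen wide because the features are pooled and PCA-reduced on at most a
  couple hundred frames, where extra channels add no usable rank), and a
  nearest-upsample decoder (16→8→4) whose final 2× step is a parameter-light
  upsample + 1×1 conv: full-resolution 3×3 convolutions dominate CPU cost
  while contributing little to reconstructions of Gaussian-smoothed frames.
* **Segmenter**: a U-net of the same family — per stage a 3×3 conv (skip
  tap) plus a stride-2 conv, skip concatenation on the way up, sigmoid
  1×1 head giving per-pixel calcific probabilities, thresholded at 0.5.

Training uses class-weighted binary cross-entropy with weights inversely
proportional to class prevalence and summing to one (`auto` computes the
prevalence over the training set as a whole, not per batch), Adam, and
early stopping: stop when validation loss has not improved for `patience`
(default 5) consecutive epochs, restore the best epoch's weights. The
final model of an experiment cell is retrained on the full training set
for the cross-validation's average stopped-epoch count.

### Evaluation

Pixel-level per-class F1 is pooled over the evaluation set (a per-frame
variant exists). Average precision is the step-wise area under the
precision–recall curve; frames without a single positive truth pixel make
PR undefined and are excluded, with the retained count reported.
PR is used instead of ROC throughout because the classes are heavily
imbalanced (~10% calcific). Clinical lesion attributes are computed from
lumen-aligned masks: angle = (A-lines containing lesion) × angular pitch;
depth = minimum first-lesion-row in mm; thickness = mean per-A-line radial
extent in mm (the reduction is a package choice, recorded here; defaults
5 µm/px and 360°/n_alines are configurable). Bland–Altman reports the mean
difference and bias ± 1.96·SD limits. Paired model comparisons use the
paired t-test (with an exact two-sided sign-flip permutation fallback when
the differences are constant) and the fewer-VOIs comparison uses a
one-sample Wilcoxon signed-rank test against the baseline AP.

### Experiment protocol

VOIs — never frames — are the unit of every split. The VOI set is
partitioned into `n_iterations` (default 4) stratified held-out sets whose
union covers each VOI exactly once; per iteration the remaining VOIs go
round-robin into `k` (default 5) label-stratified folds. Hyperparameters
(learning rate × batch size) are grid-searched on the mean test-fold
calcific F1; within the cross-validation only sampler-selected frames
carry labels — that is the premise of annotation reduction — while
held-out VOIs are fully annotated for evaluation. The seven-model
comparison runs {all, equal×{1/2, 1/3, 1/10}, clustered×{1/2, 1/3, 1/10}}
over identical split plans and segmentation seeds, so the sampler is the
only varying factor. The fewer-VOIs experiment shuffles the training VOI
order and takes whole VOIs serially until one tenth of the training frames
is reached (the VOI crossing the budget is included whole — the protocol
collects images "until the budget is reached", and inclusion keeps rivals
at or above the budget); each of `n_shuffles` (default 10) rivals is
compared to the one-tenth-clustered baseline. When a rival's training set
reduces to a single VOI, VOI-level folds are impossible and the model
falls back to a frame-level 80/20 split with early stopping.

## The phantom generator

The generator emulates the *statistical structure* of clinical IVOCT VOIs,
not OCT physics: an eccentric lumen (sinusoidal in θ, drifting smoothly in
z), tissue as an exponentially attenuating intensity profile from the
lumen boundary, multiplicative exponential speckle (`(1−s) + s·Exp(1)`,
clipped to [0, 1]) — chosen so the log transform and Gaussian smoothing of
the preprocessing chain act on the kind of noise they were designed for —
a guidewire shadow of zeroed A-lines drifting slowly in θ, and, in
calcification VOIs, a signal-poor lesion arc (intensity × ~0.22) with a
sharp front border whose center, extent, depth and thickness drift
smoothly along z. Defaults (496 A-lines × 400 radial pixels, so the
200-pixel crop discards about half the depth; arc 160°, thickness 80 px,
depth 20 px) were fixed once so that a mixed dataset at the study's 26:34
normal:calcification VOI proportions carries ≈10% calcific pixels in the
cropped, lumen-aligned view. VOI lengths span 10–200 frames.

Archetype planting — building a VOI from contiguous blocks of distinct
lesion morphologies, including `None` (plaque-free) blocks — is a testing
device for cluster-recovery and sampler-comparison experiments, not a
claim about anatomy.

What the phantom does **not** model: realistic attenuation coefficients or
catheter optics, side branches, red thrombus, stent struts, motion
artifacts, or annotation noise. Passing tests therefore demonstrate that
the pipeline's machinery behaves as specified on data with the right
*structure*; they do not certify clinical segmentation accuracy.

## Scales used in the shipped tests

The test suite runs the full selection pipeline at reduced scale so the
whole suite completes on one CPU in minutes: unit tests use 96×80-pixel
frames (64-pixel crop); the sampler-direction experiment uses 64×64 frames
(48-pixel crop), 10 VOIs of 10–30 frames, a (8, 16, 32) U-net, and 60-epoch
training; the autoencoder acceptance check runs the full 496×400 geometry
and the complete 100-epoch schedule. Reported effect directions at these
scales match the full-scale expectation (clustered ≥ equal at ratio 1/10;
fewer VOIs underperform), with absolute F1/AP values well below clinical
scale — the training sets are tiny by construction.

## Numerical choices and edge cases

* Integer pixel shifts; masks nearest-neighbour through all geometry.
* Per-frame min–max after the log; a constant frame maps to zeros.
* `log_epsilon = 1e-6`; BCE probabilities clipped at 1e-7.
* PCA on identical frames returns one constant component with a warning.
* k-medoids ties (equal costs, equidistant points) break to the lowest
  index; the `seed` argument is accepted for interface symmetry but PAM as
  implemented is fully deterministic.
* Degenerate training sets (single-class prevalence) make `auto` class
  weights raise rather than silently proceed.
* All randomness flows from explicit seeds through `numpy` SeedSequences;
  per-VOI sampler seeds are derived as `SeedSequence([master, voi_index])`
  so plans are independent of VOI processing order.

## Known limitations

* The conv engine supports exactly the layer set these networks need
  (3×3/1×1 convs, stride 1–2, ReLU/sigmoid, nearest upsample); it is not a
  general autodiff framework.
* PAM is O(k·n²) per swap pass — fine for per-VOI frame counts (≤ 200),
  not meant for thousands of points.
* The equal-spacing/clustering comparison at desk scale uses small
  networks whose absolute accuracy saturates well below published
  clinical-scale results; only directions and contracts are asserted.
* Optimal cluster count selection (silhouette, gap statistic) and active
  learning are out of scope by design.
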