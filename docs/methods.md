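# Methods

`spinefat` implements an automated pipeline that segments lumbar vertebral
bodies on 4-channel water-fat (Dixon/IDEAL) MR series with a 2D U-Net and
quantifies the per-vertebra bone-marrow-fat (BMF) fraction, together with the
full evaluation battery used to judge such pipelines (overlap and
classification metrics, chance-corrected rater agreement, ROC/PR areas with
DeLong uncertainty, Bland-Altman agreement, and test-retest repeatability).
Because clinical water-fat series of the lumbar spine are rarely shareable,
the package ships a synthetic spine-phantom generator with voxel-accurate
ground truth; every stage and every statistic is testable end to end against
known truth.

## Data model

A Dixon series is four co-registered volumes — water signal, fat signal,
fat-fraction (FF, percent) and R2* (1/s) — of shape `(n_slices, 256, 256)`
with 20 sagittal slices by default. Canonical orientation: slice index runs
left-to-right through the sagittal stack, rows run superior-to-inferior,
columns anterior-to-posterior. FF maps are stored in percent and clipped to
[0, 100] exactly once, at read time. Intensities are never normalised at the
I/O layer; the segmentation model consumes the channels at their stored
values.

## Segmentation model

The segmenter is the classic depth-4 U-Net: a contracting path of
(3×3 conv → ReLU) ×2 blocks with 2×2 max-pooling, 64 base filters doubling
per level, an expansive path of 2× nearest-neighbour upsampling, channel
halving, skip concatenation and two more convs per level, and a 1×1 sigmoid
head. `model_scale` multiplies the filter counts so reduced models train on
one CPU; the architecture is otherwise unchanged across scales. The network,
backpropagation and Adam are implemented in NumPy (`spinefat._nn`), with
convolutions lowered to matrix multiplies via im2col; all arithmetic is
float32 and all randomness flows through one seeded generator, so training
and inference are bit-reproducible on a fixed BLAS.

Slices are independent 2D samples; every slice of every training subject
enters training, including the majority that contain no vertebra. The
validation split holds out whole subjects (default fraction 7/31), never
slices. Early stopping monitors validation loss with configurable patience
(default 10) and restores the best-validation weights. Default optimiser
settings are Adam with learning rate 1e-4 and batch size 4. Probability maps
are binarised at threshold 0.5 with a strict `>` (ties map to background) —
tie handling is unspecified in common practice, so we fix and document it
for bit-reproducibility.

### Loss and training stability

The headline loss is the soft-Jaccard (Jaccard distance) with smoothing term
`s` (default 100):

    L = 1 − (Σ t·p + s) / (Σ t + Σ p − Σ t·p + s)

summed per slice, averaged over the batch. Two numerical choices required
care on a single-CPU step budget (a few thousand Adam steps, versus the
~15,000 a full-scale GPU training schedule would take):

1. **Scale-aware initialisation.** The four channels differ by orders of
   magnitude (water/fat ≈ 0.2, FF ≈ 0–100, R2* ≈ 30–150). Since the data are
   deliberately not normalised, He-initialised first-layer activations start
   saturated. At fit time the per-channel mean/std of the training slices is
   folded into the first convolution's weights and bias — the layer computes
   what it would on standardised input while the data themselves stay
   untouched, and the adjustment travels with the checkpoint.
2. **Cross-entropy stabiliser.** The Jaccard gradient is proportional to
   `p(1−p)` and vanishes once the sigmoid saturates. With rare positives
   (~2% of pixels; most slices are vertebra-free), the all-background
   solution is an *absorbing* basin: experiments at several scales and
   learning rates (1e-4 … 3e-3, with and without batch pooling, gradient
   rescaling, or a smaller Adam epsilon) all collapsed into it and froze.
   Training therefore adds a small binary cross-entropy term,
   `L_total = L_jaccard + w·BCE` with `w = 0.1` by default: its `p − t`
   gradient never vanishes and keeps rare positives recoverable. This is the
   standard remedy for Dice-family losses under heavy class imbalance. The
   Jaccard term dominates the optimum; `w = 0` restores the bare loss.

## Phantom generator

The generator emulates the statistical structure the pipeline assumes, not
MR physics. Anatomy: a lordotic column of five rounded-rectangular
(superellipse, exponent 4) lumbar bodies with disc gaps, visible on a
contiguous block of 5–7 mid-stack slices, shrinking elliptically toward the
block's lateral edges so the half-area inclusion rule has work to do. Each
body carries a dark cortical rim (default 2 px at 256², excluded from the
ground-truth mask, as raters contour marrow up to but not including cortical
bone) and a homogeneous trabecular fat fraction drawn from
Normal(33.1, 8.0)% truncated to [5, 70]% — 33.1% is the population mean the
pipeline targets; 8.0% is a generator choice representative of adult lumbar
marrow variability. Confounders make segmentation non-trivial: a
high-FF (90%) subcutaneous fat band, low-FF (8%) paraspinal muscle, and
intermediate-FF (15%) intervertebral discs. R2* is high inside trabecular
bone (150 1/s) and on the rim (120), low elsewhere, with smooth variation.

Channel synthesis per voxel: `fat = S·FF/100`, `water = S·(1−FF/100)` for a
smooth intensity field `S` (≈1 in tissue, 0.04 in air). Independent Gaussian
noise with SD `noise_sd × mean tissue signal` (default 0.05) is added to the
water and fat channels, both are clipped at zero, and the FF map is
*recomputed* from the noisy channels and clipped to [0, 100] — preserving the
ratio coupling `fat/(fat+water)` of a real two-species reconstruction. The
noise model is additive Gaussian rather than Rician: simple, controllable,
and adequate at this SNR regime, with analytically tractable propagation.
Within-body FF texture is a smooth zero-mean field with SD
`ff_heterogeneity_pct` (default 2%).

With zero noise and zero heterogeneity the mask-mean FF of each body equals
its assigned truth to float precision — the closure regime the quantification
tests exploit. An optional T12/sacrum mode adds partially imaged bodies
clipped by the superior/inferior image border, exercising the logic that
restricts analysis to L1–L5. Cohorts draw per-subject anatomy (body size,
curvature, mean FF) from documented uniform ranges with per-subject seeds
derived from one master seed; test-retest mode re-realises only the noise.

What the phantom does *not* emulate — coil sensitivity profiles,
chemical-shift artefacts, field-map errors, pathology (fractures, Modic
changes), partial-volume blur at body boundaries — bounds what passing tests
show: they validate the pipeline's logic and statistics, not its clinical
segmentation accuracy.

The simulated rater dilates or erodes each body by a signed pixel bias and
perturbs the signed distance to the contour with a smooth seeded field,
emulating systematic over/under-contouring plus hand jitter. It refuses to
produce masks in which a body is annihilated.

## ROI extraction and level assignment

The binarised prediction is decomposed per slice into 8-connected components
(diagonal pixel bridges occur at ~1.4 mm in-plane resolution); components
below `min_area_px` (default 20) are discarded as binarisation speckle.
Components are linked across adjacent slices into body tracks by
nearest-centroid matching within a radius (default 15 px). Tracks touching
the superior or inferior image border are partially imaged adjacent bodies:
they are labelled T12 (upper half) or S1 (lower half) and excluded. Of the
interior tracks, the five with the largest peak area are labelled L1–L5 in
superior-to-inferior order; with fewer than five, a warning is issued and
labels are assigned top-down.

The inclusion rule keeps, per level, the slices whose component area
exceeds half of that body's cross-sectional area. The reference area is the
**maximum component area over slices for that body** — the most stable
per-body proxy derivable from the mask alone — and the comparison is strict
(`area > 0.5 × reference`, reading "more than half" literally). This
reference-area interpretation is the single most consequential free choice
in the module; the median or a designated mid-sagittal slice are defensible
alternatives and the helper is small enough to swap.

## BMF quantification

For each retained ROI the arithmetic mean of the FF map is taken slice by
slice; the per-body BMF is the **unweighted mean of the slice means** — each
slice contributes equally regardless of pixel count (a pixel-pooled mean is
available but not the default, because slice-wise averaging is the
convention the pipeline reproduces). Non-finite FF pixels (possible after
division by near-zero total signal) are excluded from slice means and
counted in the report.

## Evaluation statistics

* Confusion counts are tallied, by default, only over slices where the
  reference segmentation contains vertebrae ("vertebra slices only"), the
  scope in which segmentation performance is conventionally reported;
  whole-volume scope is a flag.
* DSC = 2TP/(2TP+FP+FN) and IoU = TP/(TP+FP+FN); the identities DSC ≡ F1 and
  DSC ≡ 2·IoU/(1+IoU) are asserted in tests. Empty-union cases with both
  masks empty in scope count as perfect agreement.
* Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from per-annotator empirical
  marginals. For two classes, linear weighting coincides with the unweighted
  statistic (implemented generally, degenerate case documented). Two
  constant, equal raters give κ = 1; constant but different raters give
  κ = 0 with a warning.
* ROC AUC is the tie-aware normalised Mann-Whitney statistic; its standard
  error uses DeLong's structural components (per-positive and per-negative
  placement values), with the 95% CI `AUC ± 1.96·SE` clipped to [0, 1].
* PR AUC uses the step-wise average-precision summation Σ ΔR·P without a
  precision envelope.
* Bland-Altman differences are oriented **manual − automatic**, so a
  negative bias means the automatic method reads higher. LOA = bias ±
  1.96·sample SD (n−1); the bias CI is bias ± 1.96·SD/√n.
* Repeatability: ICC(2,1) (two-way random effects, absolute agreement,
  single measure) from the paired-measurement ANOVA decomposition — the form
  implied by random subjects and fixed occasions; identical test-retest
  input yields exactly 1. Short-term precision error is the RMS over pairs
  of the two-point CV (pair SD = |difference|/√2, CV = SD/mean·100).

## Problem sizes used in tests and the acceptance script

Full-scale training (64 base filters at 256×256) is supported by the code
but the shipped end-to-end checks run a reduced configuration chosen as a
faithful scaled analogue: 64×64 phantoms (cortical rim 1 px), a 20-subject
cohort split 16/4 by subject, `model_scale 0.25` (16 base filters, depth 4),
batch size 4, learning rate 1e-4, and at most 12 epochs with early-stopping
patience 4 — enough for held-out Dice well above 0.8 on phantom anatomy.
Metric implementations are verified against deliberately naive brute-force
oracles (per-pixel tallies, all-pairs AUC counting, exhaustive threshold
sweeps, flood-fill component counting) on hundreds of random small
instances, and against independent reference implementations
(scikit-learn, pingouin) where available.

## Known limitations

* The NumPy U-Net trains practically only at reduced scale; full 256×256 /
  64-filter training would take hours per epoch on one CPU.
* Level assignment assumes a roughly vertical, fully imaged lumbar column;
  severe scoliosis or missing bodies degrade the top-down labelling.
* The phantom's homogeneous per-body FF makes quantification closure exact;
  real marrow heterogeneity enters only as smooth texture.
* DICOM support is deliberately minimal: Secondary Capture masks and plain
  single-frame channel series; no PACS networking, no multi-frame objects.
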