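# Methods

## The task and the pipeline

A CNV lesion on OCTA is graded *active* when at least three of five
morphological criteria are present: well-defined (lacy-wheel / sea-fan)
shape, tiny branching vessels, anastomoses and loops, a peripheral arcade
at the vessel termini, and a perilesional hypointense halo on the
choriocapillaris slab. The pipeline mirrors how a grader works: first
isolate the lesion and the two auxiliary regions (arcade margin, halo),
then judge each criterion on the region that carries it, then apply the
≥3-of-5 rule.

Inputs are co-registered pairs of 2-D grayscale en-face projections —
an outer-retina slab (where the neovascular network is visible) and a
choriocapillaris slab (where the halo lives) — with intensities in [0, 1],
row-major indexing, origin top-left. The reference acquisition grid is
304 × 304 samples over 6 × 6 mm².

## SEG-CNV: the segmentation U-Net

A four-level encoder–decoder with skip connections. Per level: two 3 × 3
convolutions + ReLU; 2 × 2 max pooling down; nearest-neighbour upsampling
followed by a 2 × 2 convolution up; decoder blocks convolve the
concatenation of the skip and the upsampled path; a final 1 × 1
convolution + sigmoid yields one foreground probability per pixel.
Dropout (rate 0.2) sits on the two deepest blocks (deepest encoder block
and bottleneck), the part of the network most prone to overfitting on
small cohorts.

The published description of this architecture fixes only the headline
trainable-parameter budget (~1.6 M at 128 × 128 × 1), not the per-level
channel counts. The reference configuration here is encoder widths
(16, 32, 64, 128) with a 192-channel bottleneck, whose layer-wise total is
**1,576,145** — inside the [1.55 M, 1.65 M] budget band and an order of
magnitude below the ~30 M of the classic U-Net. The count is verified in
the tests against an independent closed-form sum Σ(k·k·c_in·c_out + c_out)
over all convolutions.

Training minimises the soft Dice loss
`L = 1 − (2 Σ p·g + ε) / (Σ p + Σ g + ε)` with ε = 1e-6 (avoids 0/0 on
empty masks; makes the both-empty case exactly 1 − 1 = 0). The evaluation
Dice coefficient uses the same ε, so `coefficient = 1 − loss` holds
identically on binary inputs. Defaults: Adam, learning rate 3e-4, batch 8,
50 epochs. The 3e-4 rate matters: at 1e-3 the sigmoid saturates toward the
empty mask early in training and the Dice gradient cannot recover it —
single-pair memorization fails — while at 3e-4 a single pair is memorized
to Dice ≈ 0.97 and 50 phantoms are learned to held-out Dice ≈ 0.98.
Probabilities are thresholded at 0.5 with ties to foreground; masks are
resampled to the native image size by nearest neighbour. A small grid
search utility over learning rate × batch size is exposed
(`grid_search_segcnv`). All stochastic stages (init, shuffling, dropout,
augmentation sampling) derive from one experiment seed; training is
bit-reproducible.

## SEG-PA: peripheral-arcade extraction

Three deterministic primitives, composed:

1. `binarize_vessels`: pixel is vessel iff its intensity strictly exceeds
   the local mean over a `window` minus `offset` × (local range), computed
   with reflected borders and evaluated only inside the (dilated) lesion
   mask. Constant regions binarize to zero by the strictness rule.
2. `invert_within_mask`: inter-vessel spaces become foreground inside the
   mask; everything outside is zero.
3. `ring_mask`: `dilate(mask, outward) AND NOT erode(mask, inward)` — a
   band *straddling* the lesion boundary (the arcade sits on the margin
   itself, so a band only outside the boundary would miss half of it).

The arcade mask is the ring ∧ inter-vessel spaces: the open margin. A
closed arcade reduces this open area; a dead-tree margin leaves more of
it — downstream classification uses the pattern, not a fixed threshold.

Parameter defaults (at the 304-px grid, scaled proportionally for other
sizes, all exposed): window 15, offset **−0.15**, disk structuring
elements, outward = inward = 5 px. The negative offset tightens the vessel
criterion to mean + 0.15 × range: with any positive offset roughly half of
all vessel-free textured pixels exceed their own local mean and binarize
as vessel, which drowns the arcade's contribution to the open-margin area;
with the tightened criterion only genuinely bright structures count, and
removing the arcade strictly increases the open margin on every phantom
tested. Defaults were fixed once on phantoms and frozen.

## SEG-DH: dark-halo extraction

The choriocapillaris image is first enhanced with contrast-limited
adaptive histogram equalization (tiles ≈ 1/8 of the image side, clip limit
0.02 in scikit-image's normalized convention; constant images pass through
unchanged). Seeds are the lesion contour offset one pixel outward, kept
only where the enhanced intensity is *hypointense* (strictly below
mean − 0.25 × std): the halo is a dark structure, and without this gate a
uniformly bright choriocapillaris would grow into the entire search
annulus, since every pixel is trivially similar to bright seeds.

Region growing uses a running-mean similarity criterion: a 4-connected
neighbour is absorbed iff its intensity differs from the current region
mean by ≤ tolerance (default 0.15). The frontier is a FIFO queue, seeds
sorted row-major, neighbours visited row-major — the result is fully
deterministic. 4-connectivity for growth pairs with 8-connectivity for
contours, the standard combination that avoids topological paradoxes. The
alternative fixed-seed-mean criterion is kept in the tests as an
independent oracle; on piecewise-constant fixtures the two coincide. The
grown region is intersected with NOT-mask and a bounded search annulus
(default 50 px outward, scaled).

## The five classifier heads

| criterion          | input              | model            | trained layers        |
|--------------------|--------------------|------------------|-----------------------|
| branch             | CNV ROI            | transfer (VGG16) | FC head only          |
| shape              | CNV ROI            | transfer (VGG16) | last 3 convs + FC     |
| anastomoses/loops  | CNV ROI            | transfer (VGG16) | last 1 conv + FC      |
| peripheral arcade  | PA mask            | from scratch     | all layers            |
| dark halo          | DH mask            | transfer (VGG16) | FC head only          |

The transfer backbone is the canonical 13-convolution VGG16 (the full
reference network with its 4096/4096/1000 classifier totals 138,357,544
parameters; the package computes this closed-form). The new head is
global-average-pool(512) → dense(419) → dense(1012) → dense(1) + sigmoid;
with the backbone fully frozen its trainable total is exactly
641,000 = 513·419 + 420·1012 + 1013. The head widths are a recorded
reconstruction chosen to land on that total; "last N convolutions" follows
the usual fine-tuning convention. Freezing is real, not cosmetic: frozen
parameters are skipped by the optimizer entirely and stay bit-identical
through training (asserted in tests). Pretrained ImageNet weights are
optional (an `.npz` path); with none given the backbone is seeded-random
with the identical architecture and freeze policy — the architecture and
freeze mechanics are the reproducible content, the weights are an external
artifact.

The arcade and halo heads consume the bare binary masks (they are the
segmentation block's outputs for those criteria); mask-times-image variants
were considered and rejected to keep each head's input the region pattern
itself. The scratch net is 4 × (3 × 3 conv + ReLU + 2 × 2 pool) with
widths (16, 32, 64, 128) and one dense output, 105,345 parameters, input
128 × 128 × 1. Transfer inputs are bilinearly resized to 224 × 224,
replicated to 3 channels and normalized with the standard ImageNet
per-channel mean/std (the GAP head makes the backbone size-agnostic, so
smaller inputs are accepted for cheap experiments).

Training: binary cross-entropy on logits (numerically stable form), Adam,
lr 1e-4 (transfer) / 1e-3 (scratch), batch 8, 30 epochs; augmentation
(rotation ≤ ±25°, zoom 0.8–1.2, flips, shear ≤ ±10°) never touches labels.
When a model has a frozen prefix and augmentation is off, the prefix
activations are computed once and cached, so the frozen backbone is never
re-evaluated during epochs.

## Evaluation

Pixel overlap by Dice = 2TP/(2TP+FP+FN) (which equals F1 on pixels);
label agreement by accuracy, F1, sensitivity, specificity from the 2 × 2
confusion matrix. Undefined ratios (zero denominators) are reported as NaN
with a warning rather than silently as 0, so fold averages are not
corrupted; fold aggregation is the unweighted mean with per-fold values
retained for violin-style export. Percentages round half-up to two
decimals. Cross-validation is subject-wise and nested: subjects (never
images) are shuffled by seed and partitioned into k near-equal outer folds,
each outer training set into inner folds for hyperparameter selection;
every image follows its subject, so no subject can appear on both sides of
any split (property-tested on 1000 random subject sets).

## The phantom generator

The generator emulates the *structure* of the study conditions — 304 × 304
en-face pairs, a central lesion of ~60 px (~1.2 mm) radius, cohorts with
subject grouping (e.g. 50 subjects × 2 images, echoing a 130-images /
101-patients cohort shape), per-feature prevalences near one half — with
one rendering rule per activity criterion: radial spokes always; chords
closing a sea-fan silhouette when the shape criterion is on, 2–4 long
low-curvature filamentous strands leaving the disk when it is off; short
high-curvature twigs for branching; circumferential mid-radius links for
anastomoses/loops; a near-closed marginal arc with a few gaps for the
arcade; multiplicative darkening (factor 0.45) of an annulus of width
12 px for the halo. Vessel skeletons are Bresenham-rasterized (no
anti-aliasing) and thickened by disk dilation, so ground truth is exactly
countable; background is band-pass-filtered noise with amplitude ≤ 0.25 of
the vessel intensity on the outer-retina channel (the outer retina is
normally avascular and dark) and a brighter granular texture on the
choriocapillaris. Each feature draws from its own child stream of the one
seed, so toggling a feature provably changes only that feature's pixels;
subjects carry a random intensity gain and lesion-radius offset so
subject-wise CV differs meaningfully from image-wise CV. No quantitative
morphometry of real lesions was available to fit against, so these
defaults are plausibility choices, frozen.

What the phantoms do **not** model: OCTA speckle and decorrelation noise
statistics, projection artifacts, motion/shading artifacts, eccentric or
multifocal lesions, the intensity statistics of real choriocapillaris
flow deficits. Passing phantom-recovery tests therefore demonstrates that
the implementation learns and extracts what it is supposed to under
controlled, separable conditions — not that clinical-grade accuracy is
reached on real data, which would require the (non-public) clinical
cohort.

## Problem sizes used in the test suite

The recovery experiments run at deliberately modest sizes chosen as the
package's own test-time conditions: segmentation is trained on 50 phantom
pairs with 10 held out, at a 64 × 64 model grid for 15 epochs (held-out
Dice ≈ 0.98 against the ≥ 0.80 bar); the arcade head trains on 50
seg-pa masks with 20 held out (accuracy 1.0 against the ≥ 0.8 bar) next
to a label-randomized null control built with zero empirical
label–feature association (a plain label permutation retains chance-level
agreement with the truth, which a separable feature converts back into
real accuracy); the halo extractor is scored on full-size 304-px phantoms.

## Known limitations

- The numpy engine is CPU-only and single-threaded beyond BLAS; it is
  sized for the package's reference architectures, not for large-scale
  training.
- The published architecture figure does not fix channel counts or the
  dropout placement; the reference configuration is an explicit
  reconstruction that honours the stated parameter budget, not a claim of
  layer-for-layer identity. Likewise the "around 641,000" trainable count
  is consistent only with the FC-only freeze configuration (a single deep
  VGG convolution alone exceeds 2 M parameters), and is treated as such.
- Region-growing behaviour on real, noisy halos will be more
  tolerance-sensitive than on phantoms; the tolerance, CLAHE and gate
  parameters are exposed for that reason.
- The activity score consumes hard labels; probability calibration of the
  heads is out of scope.
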