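# Methods

`cytofna` is a desk-scale re-implementation of a whole-slide thyroid
fine-needle-aspiration (FNA) cytology diagnosis pipeline. Clinical slide
archives are not redistributable, so the package is built around a synthetic
smear generator that provides exact ground truth at every stage; every model
in the pipeline is trained and validated on that generator. This note
documents the models, the conventions chosen where the design was genuinely
open, and what the synthetic results do and do not show.

## Pipeline overview

A slide is an ordered set of RGB tiles. Processing stages:

1. *(optional)* image appearance migration (IAM) to a reference domain;
2. nuclear segmentation (pyramid-fusion U-Net, per-pixel foreground
   probability);
3. component-wise HSV debris rejection (red-blood-cell colour band);
4. post-processing into nucleus/cluster detections (distance-transform
   watershed splitting, per-object mean-probability score);
5. 19-feature nuclear morphometry;
6. 17-class cell classification (large-kernel-attention network) plus an
   independent morphology GBT, combined by an agreement gate on the
   papillary (C1–C3) and benign-follicular (C6–C8) classes;
7. aggregation into a 104-attribute slide feature vector;
8. two-step diagnosis: the TBS-I adequacy rule, then a gradient-boosted
   classifier (3-class II/V/VI or 2-class II vs V+VI);
9. *(optional)* cascade fusion with a binary BRAF-V600E classifier that
   resolves TBS V into II (wild-type) or VI (mutant).

## Synthetic smear generator

Patches emulate liquid-based Papanicolaou or H&E smears: textured elliptical
nuclei over pale glass, with class-specific styles — benign follicular cells
small/round/dark; papillary-carcinoma classes larger, paler, with irregular
membrane outlines; the nuclear-groove class carries a dark linear fold, the
pseudo-inclusion class a bright intranuclear disk; macrophages are large and
tan, lymphocytes tiny and dark. Red-blood-cell debris is rendered as small
saturated-red disks **without** a mask label (a deliberate true-negative
population for the HSV filter); faint colloid smears are likewise unlabelled.
Clusters are unions of ≥ 2 overlapping ellipses sharing one instance label,
with the member count stored so group semantics can be ground-truthed.

Slide ground truth is a deterministic function of the generated counts:

* **TBS I** iff `10·(N_C1 + N_C6) + 5·(N_C2 + N_C7) < 60` (the same weighted
  adequacy rule the diagnosis stage applies, evaluated on true counts);
* otherwise the label follows the realized atypical fraction
  `f = (C1+C2+C3+C4+C5) / (C1+…+C8)`: **VI** if `f > 0.5`, **V** if
  `0.1 < f ≤ 0.5`, **II** otherwise.

The (0.1, 0.5] band for TBS V is a fixture convention chosen so that all four
output labels occur; both thresholds are config-exposed (`tbs_v_lo/hi`).
BRAF status is sampled from a logistic link on the atypical fraction
(slope 10, centred at 0.5), strong enough that the gene classifier is
learnable from slide features yet noisy enough to be non-trivial.

Cohorts (`sample_cohort`) draw 15% near-acellular slides (TBS I regime) and
otherwise an intended atypical fraction uniform on [0, 1]; the default mix
places 0.8 probability mass on epithelial classes plus 0.2 lymphocytes, so
the realized fraction is unbiased for the intended one. The atypical share
is split 0.7/0.15/0.15 over C1/C4/C5: papillary-carcinoma cells dominate
real malignant smears, and the groove/pseudo-inclusion phenotypes are a
minority — an equal split would also starve the adequacy rule (which counts
only the PTCA/TFECA/PTCB/TFECB roles) on high-grade slides. Default cohort
geometry is 3 tiles of 128 px with 6–10 nuclei per tile — sparse enough
that nuclei rarely merge at this resolution, dense enough that adequate
slides clear the 60-cell adequacy threshold with a comfortable margin.

All randomness flows through one `numpy.random.Generator` per call;
identical `(config, seed)` pairs are byte-identical.

**What the generator does not emulate:** chromatin texture statistics of real
nuclei, three-dimensional focal planes, smear artifacts (folds, air-drying),
overlapping *cytoplasm* (only nuclei are rendered), and the long-tailed class
frequencies of clinical archives. Passing tests therefore demonstrate that
the pipeline machinery is correct and recovers the generator's parameters,
not that clinical-grade accuracy would be reached on real slides.

## Neural-network core

No GPU framework is used: `cytofna.nn` is a compact CPU implementation
(im2col convolutions, depthwise and dilated variants, batch norm, max-pool,
nearest-neighbour upsampling, GELU/ReLU, AdamW with cosine annealing) with
explicit backward passes, verified against finite differences in the test
suite. Float32 throughout; weight initialisation is He-normal from a seeded
generator, so builds and training runs are exactly reproducible.

## Segmentation network

Encoder–decoder with skip connections; stage widths double from
`base_width`. With `pyramid_fusion` on, every decoder scale is projected by
a 1×1 convolution, upsampled to full resolution, concatenated and fused by a
1×1 convolution before the single-logit head — a feature-pyramid reading
that adds multi-scale context at negligible parameter cost. The "tiny"
preset (depth 3, width 8, 128-px input, ~30 k parameters) trains on one CPU
in a few minutes and sits far below 20% of the parameter count of the
VGG16-backbone DeepLab-v1-like reference (`deeplab_v1_reference_params`,
~41 M), the compactness constraint the design targets.

Training loss is pixel-wise binary cross-entropy plus soft Dice with equal
weights — BCE alone under-weights the sparse foreground, Dice alone is
unstable on empty tiles. Defaults: AdamW, lr 1e-3 cosine-annealed, batch 4,
30 epochs on 50 patches. The training-loss trace is monotone non-increasing
after 5-epoch moving-average smoothing, up to a 5% relative tolerance that
accommodates plateau noise after convergence.

## Detection post-processing

Connected components of the thresholded probability raster. Components whose
median HSV colour falls in a reject band are dropped *whole* (component-wise,
never pixel-wise, which would fragment nuclei); the default band is
saturated red (hue ≤ 0.05 or ≥ 0.95, saturation ≥ 0.5), config-exposed
because it is stain-dependent. Range bounds are half-open at the top except
at 1.0. Components above `max_single_area` (4000 px²) are split by a
watershed on the negative distance transform seeded at distance maxima at
least `min_peak_distance` (7 px) apart; objects are clusters when their area
exceeds `cluster_area_threshold` (1200 px²) or they contain ≥ 2 seeds;
objects under `min_area` (30 px²) are discarded. These defaults were
calibrated once on the synthetic fixture at 256-px tile scale and are all
config-exposed; `cytofna.pipeline.tile128_config()` provides the rescaled
preset used for 128-px cohort tiles (split above 700 px², 5-px peak
separation). With splitting disabled the stage reduces exactly to
connected-component labelling (property-tested). Coordinates are 0-based,
half-open boxes, row-major rasters, origin top-left.

## Morphometry

The 19-feature vector is this package's documented convention: 11 geometry
features (area, perimeter, equivalent diameter, major/minor axis, aspect
ratio, eccentricity, circularity 4πA/P², solidity, extent, orientation in
(−π/2, π/2] from the x-axis) and 8 intensity/texture features (gray
mean/std/min/max, HSV channel means, Sobel gradient energy), covering
nuclear-membrane shape and chromatin-texture cues. Degenerate one-pixel
masks use a perimeter ≥ 1 convention and aspect ratio 1. Circularity may
slightly exceed 1 for small rasterized disks.

The morphology GBT (XGBoost, depth 4, 200 trees, η 0.2) is trained with
`reg_lambda = 0` and `min_child_weight = 0` so splits and leaves depend only
on gradient/hessian *ratios*: predictions are then exactly invariant under
dataset duplication, a property the suite checks. Regularisation comes from
tree depth, adequate for a 19-feature space.

## Cell classifier and agreement gate

The classifier follows the large-kernel-attention design: each block gates
its input multiplicatively with an attention map computed by a 5×5 depthwise
convolution, a 7×7 depthwise convolution dilated ×3, and a pointwise
convolution, followed by a residual convolutional feed-forward sub-block.
Tiny preset: 4×4/stride-4 patch embedding, two stages (widths 16/32, two
blocks each), 64-px crops; the full-size default crop is 224 px. Training:
AdamW (weight decay 0.05), cosine-annealed learning rate (1e-3 default;
the fixture training uses 2e-3, which the mixed crop set needs to converge
within 40 epochs), flips/rotations/colour jitter then random crop
(72 → 64 px). Fixture training data mixes clean single-cell renders with
crops harvested from dense rendered patches around ground-truth centroids,
so the classifier sees neighbouring cells and off-centre context exactly as
the detector produces them at inference time.

The agreement gate re-tests C1–C3 and C6–C8: a call is kept only when the
network class and the morphology-GBT class agree. Agreement is evaluated at
the *role* level (papillary vs follicular family) by default because the GBT
is trained on the 9-role reduction; exact-id matching is available by flag.
Rejected calls never enter the slide statistics. The gate only keeps or
rejects — it never relabels — and is idempotent.

## Slide features (104 attributes)

Per-role (9 roles) counts, mean/median call probability, mean/median
detection score, mean/median object area (9 × 7 = 63); mean/median of each
of the 19 morphometry features over all accepted nucleus-kind objects (38);
and three globals: total detections, cluster count, and the weighted
adequacy sum (`ADEQ-LHS`). Roles with no members use a 0 sentinel rather
than missing values so the tree models need no missing handling. Cluster
objects contribute to counts, scores and areas but not to nuclear
morphometry. The registry is versioned (`v1`) and ordered; classifiers
record the registry version and refuse mismatched features.

## Diagnosis

Stage 1 applies the adequacy rule
`10·(N-PTCA + N-TFECA) + 5·(N-PTCB + N-TFECB) < 60` (strict inequality;
weights are cells-per-large-group and cells-per-small-group, the threshold
the classical six-groups-of-ten follicular-cell convention). The printed
formula is ambiguous in its grouping; the reading above follows the prose
definition of the weights and the 60-cell convention, and is the one
implemented and tested. Slides that pass go to an XGBoost classifier tuned
by grid search (depth {3,5,7}, η {0.05,0.1,0.3}, trees {100,300}, subsample
{0.8,1.0}) under stratified 5-fold cross-validation; the best configuration
is refit on all data. The 2-class variant merges V and VI before training.
The gene classifier is a binary XGBoost on the same 104 features. Cascade
fusion maps (V, 0)→II and (V, 1)→VI and passes everything else through;
the gene model is consulted only when the image model outputs V.

Evaluation metrics are binomial proportions with Wald intervals
`p ± z·√(p(1−p)/n)`, z = 1.959964, clipped to [0,1]. For indeterminate-
category cohorts every sample is positive-eligible, so sensitivity is the
fraction predicted in the positive set.

## Image appearance migration

Appearance profiles are per-channel mean/std (plus 1st/99th percentiles,
stored but unused by the default map) of cell-foreground pixels in CIELAB.
Cytology needs its own foreground mask — smears are dispersed cells on bare
glass — so the mask marks pixels clearly more saturated than, or darker
than, the glass estimate (tile-median saturation/luminance, which keeps the
mask stable under global tints), closed morphologically with small objects
removed. H&E is a `MaskParams` preset, not a separate algorithm. Migration
applies the Reinhard-style affine match per channel (σ_src = 0 → gain 1) to
foreground pixels, blending the background through a Gaussian-feathered mask
(radius 3 px) to avoid halos; the mapping function is pluggable. The source
profile is always estimated once per slide and applied tile-by-tile,
preventing tile-to-tile flicker.

## Problem sizes used by the validation suite and acceptance script

Chosen as the package's desk-scale study conditions: segmentation trains on
50 patches (128 px) for 30 epochs; the cell classifier on 480 crops (80 per
class, six visually distinct classes) for 40 epochs; the slide classifiers
on the pipeline features of 150 generated slides (3 tiles each) with the
full hyperparameter grid; end-to-end evaluation uses 200 held-out slides.
All seeds derive from a single CLI seed.

## Known limitations

* Only six of the 17 schema classes have distinct rendered styles (C9–C17
  are schematic placeholders); the classifier head still outputs 17 logits.
* The generator's TBS V band is a fixture convention, not a clinical
  calibration; cohort-level accuracies here say nothing about clinical
  sensitivity/specificity.
* The appearance-migration map is global-affine per channel within the
  foreground; spatially varying stain gradients are out of scope. Deeply
  stained pixels near the sRGB gamut boundary lose variance to gamut
  clipping on 8-bit re-quantization, so double migration is idempotent for
  the bulk of pixels but not pixel-exact at the gamut edge.
* The foreground mask assumes cells are a minority of tile pixels; fully
  confluent tiles would bias the glass estimate.
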