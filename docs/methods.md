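# Methods

## Overview

`sporeseg` segments bacterial spore TEM micrographs into 8 classes —
Badreg (1), coat (2), core (3), cortex (4), exosporium (5), interspace
(6), nap (7), background (8) — at 1/16 of the input resolution. The
pipeline is: preprocessing → convolutional feature extraction →
random-forest pixel classification → evaluation and layer quantification.
Label 0 marks unannotated pixels and is excluded from training and
scoring everywhere.

## Preprocessing

Micrographs are resized to a 16-divisible working size (bilinear for
pixels, nearest-neighbour for masks, so masks can never acquire labels
they did not have) and min-max normalized per image to [0, 1]; a constant
image maps to all zeros, and normalization is idempotent. Normalization
is per image rather than per dataset because no global statistics are
assumed to be available at inference time.

Augmentation is a fixed, deterministic set of six invertible geometric
transforms applied identically to image and mask: rotations by 90°, 180°
and 270°, horizontal and vertical flips, and one scale jitter (+10% zoom
in place, recropped). Right-angle rotations of rectangular images are
performed on the padded square and centre-cropped back, so all six
outputs keep the input size. Six transforms per image expand a 64-image
training pool to 384.

Masks are aligned to the feature grid by 16×16 blockwise majority vote:
label 0 is ignored in the vote, ties break to the lowest class index, and
an entirely unannotated block stays 0. For size-preserving transforms
(flips, 180° rotation) this downsampling commutes exactly with the
transform; for 90°/270° rotations it commutes on the working aspect
family (where pad offsets are 16-aligned), which the tests assert.

## Feature extractor

A VGG-style encoder: 3-channel input (grayscale replicated), a 32-channel
stem convolution, then five blocks of widths 64/128/256/512/1024 with
2/3/3/3/3 convolutions — 15 convolutions in total, all 3×3/stride 1 with
ReLU — and a max-pool after each block. The output is the 1024-channel
post-ReLU activation grid.

Two architectural points were genuinely open and resolved as follows:

- **Pooling schedule.** Five pools with a /16 total reduction are
  reconciled by giving pools 1–4 stride 2 and pool 5 stride 1 with same
  padding. This honours both the five-pool count and the 128×104 output
  for a 2048×1664 input.
- **Conv distribution.** 15 convolutions split 1 (stem) + 2+3+3+3+3
  across the five blocks — the only VGG-like split consistent with a
  single 32-map stem followed by width-doubling blocks.

The network is implemented directly in numpy: convolutions are evaluated
as nine offset GEMMs through BLAS, with explicit backprop and an Adam
optimizer (lr 10⁻³, β = 0.9/0.999), one image per step. This keeps the
whole package deterministic on one CPU thread: same seed, same weights,
bit-identical features on repeated calls.

**Training objective.** The layer labels themselves supervise the
features: an auxiliary 1×1-convolution softmax head at the 1/16 grid is
trained with pixel-wise categorical cross-entropy against the
downsampled masks (label 0 masked out), and discarded at extraction
time. Weights are checkpointed only when the validation loss improves on
the best value seen so far, so the checkpoint epoch always holds the
minimum observed validation loss.

## Random forest

Each labeled grid cell is one sample with 1024 features. Trees are grown
on bootstrap resamples with the Gini impurity criterion
(*Gini = 1 − Σ pᵢ²*; a pure node is not expanded — no depth cap by
default), with 25 candidate features evaluated at each split and 300
trees by default. Tree induction is delegated to
`sklearn.ensemble.RandomForestClassifier`; the Gini function, the
per-tree hard majority vote and the lowest-class-index tie rule are
implemented in the package (scikit-learn's own `predict` averages
probabilities, which is not the same rule on ties).

"25 features" is interpreted as per-split candidate subsampling — the
standard random-forest rule — rather than a fixed 25-feature subspace
per tree; the alternative reading would cripple trees built from 1024
mostly-redundant channels.

A per-image cap (default 2000 cells, seeded uniform subsample) bounds
the training matrix, since a full-resolution pool (hundreds of images ×
13 312 cells) is far beyond what tree induction needs here.

## Training protocol

Three-fold cross-validation over the training pool: per fold the encoder
trains on two-thirds of the pool (optionally augmented ×7) and validates
on the rest; the fold whose best validation loss is lowest supplies the
final encoder. Features are then extracted from the full training pool
and the forest is fitted once. Folds are a seeded shuffle with remainder
items assigned to the earliest folds. Held-out evaluation never touches
the fold machinery.

Two baselines calibrate the hybrid's value: a random forest on raw
16×16 block-mean intensities (one feature per channel), and the constant
majority-class predictor.

## Evaluation

All metrics derive from one-vs-rest counts on the 8×8 confusion matrix:
accuracy (TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), sensitivity
TP/(TP+FN), F1 2TP/(2TP+FP+FN), support = row sum. Zero denominators
return 0, so a class absent from both truth and prediction contributes
zero rather than unity to macro averages. Aggregate
precision/sensitivity/F1 are macro (unweighted) means over the 8
classes. Scoring happens at the 1/16 grid; cells whose downsampled true
label is 0 are excluded, and per-image accuracy excludes (with a
warning) images with no scored cells.

## Phantoms

The generator emulates what the downstream pipeline actually consumes: a
roughly elliptical spore section with concentric layers over a bright
background. Defaults (jittered ±: centre 4%, radii 6%, gray levels 0.02,
orientation uniform):

| feature | value | rationale |
|---|---|---|
| layer radii (fraction of half-frame) | 0.40/0.60/0.70/0.80/0.86/0.92 | spore fills most of the frame, thick core and cortex, thin outer films — as in section micrographs |
| gray levels | Badreg 0.12, coat 0.22, core 0.35, cortex 0.65, exosporium 0.72, nap 0.76, interspace 0.80, background 0.85 | core/cortex/coat/background well separated; interspace/exosporium/nap deliberately within ~0.1 of each other, the trio that is confusable in real data |
| nap texture | angular dark fibres over background gray | mean intensity alone cannot separate nap from interspace |
| optics/noise | Gaussian blur σ = 1 px, additive noise σ = 0.03, clipped to [0, 1] | mild defocus + detector noise |
| ellipticity | 0.75 ± 0.05 | sectioned spores are elongated |

An off-spore debris blob carries the Badreg class so all 8 labels occur.

**Damage mode.** Chemical damage is an appearance-only perturbation: the
core, and the inner fraction `damage_level` of the cortex band (with a
short smooth shoulder), are blended toward a mottled "decomposed"
texture of mean gray 0.44 — discolored relative to the intact core
(0.35) but still nearer the core's trained appearance than the intact
cortex (0.65). The ground-truth mask is unchanged: the damaged tissue
still *is* core and cortex. Consequence: a model trained only on intact
phantoms classifies the decomposed inner cortex as core, so the
predicted core ratio rises and the cortex ratio falls on damaged spores
— the same signature used to flag core damage in real chemically
exposed spores. These phantoms deliberately do not model TEM image
formation (contrast transfer, stain granularity), crowded multi-spore
fields, or sectioning artifacts; passing tests therefore demonstrate
correctness of the pipeline's mechanics and the qualitative damage
readout, not performance on real micrographs.

## Quantification

Layer ratios divide each of coat/core/cortex by the count of all
spore-body cells (the six spore classes; background and Badreg
excluded). A `ccc` mode normalizing by coat+core+cortex only is
available. Group summaries are descriptive (mean, population SD, n);
significance testing is intentionally out of scope.

## Problem sizes

The test-suite and acceptance benchmark run the full-width encoder (15
convs, 1024 channels) on 160×128 phantoms — the same 16-divisible aspect
family as the 2048×1664 working size — with 20 training / 10 held-out
images, 2 encoder epochs, no augmentation in the benchmark folds, and a
100-tree / 300-cells-per-image forest, three seeded replicates. These
sizes keep a replicate to a few minutes on one CPU while exercising
every stage of the protocol; full-scale settings (2048×1664, 300 trees,
augmentation on) remain the library defaults. Unit tests additionally
use a narrow encoder (stem width 2, same doubling law) where only wiring,
not capacity, is under test.

## Numerical notes and limitations

- All arithmetic is float32 single-threaded; determinism holds to the
  bit for fixed seeds.
- Ties: vote argmax and block-majority both break to the lowest class
  index — one convention everywhere.
- Min-max normalization of a constant image is defined as zeros; NaN/Inf
  pixels are rejected rather than propagated.
- The encoder's training hyperparameters (optimizer, learning rate,
  epochs) are package defaults, not reproductions of any reference
  values; the extractor is supervised by the same labels the forest
  consumes, which keeps the two stages consistent but also means features
  are not transferable across label schemes.
- With few epochs the deep features are context-heavy; very small
  appearance perturbations inside a single grid cell may not flip its
  classification. The damage analysis therefore operates at
  whole-structure scale (core plus inner cortex).
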