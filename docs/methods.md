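# Methods

## Problem and model

`gasmil` grades gastric biopsy whole-slide images for four Sydney-system
features (inflammation, activity, atrophy, intestinal metaplasia; grades
0–3) from slide-level labels only, and combines five biopsy-site grades
per patient into OLGA and OLGIM stages 0–IV.

The supervision model is standard MIL: a slide is a bag of tile instances;
a bag with grade > 0 contains at least one lesion instance, a grade-0 bag
contains none. The pipeline decomposes into tiling, self-supervised patch
embedding, multi-scale splicing, weakly-supervised patch scoring with
top-k key-patch selection, transformer set aggregation to a 4-level grade,
and deterministic rule-based staging.

## Tiling

Slides are rescaled to the target resolution (area/box interpolation —
integer-factor downsampling uses an exact block mean to avoid aliasing)
and gridded row-major from the top-left; incomplete edge tiles are dropped
rather than padded so every tile honours the 224×224 contract. Grid
coordinates are 0-based. The tissue filter keeps a tile when ≥ 10% of its
pixels have HSV saturation > 0.05 and value < 250/255; glass background is
bright and unsaturated, stained tissue is not. The filter is deliberately
the simplest reproducible rule; real-slide practice often adds Otsu
thresholds or morphology, which is out of scope. A fine tile whose 2.0 MPP
parent was filtered out is dropped (`harmonize_scales`), because the
spliced embedding needs both scales.

Cross-scale correspondence is `parent = (row // 4, col // 4)`: the scale
ratio 2.0/0.5 = 4 must be integral, every fine tile has exactly one
parent, and at most 16 children share one parent.

## Contrastive pretraining

One encoder per resolution (texture statistics differ across
magnifications). Views are generated by random right-angle rotation (plus
≤ 10° continuous jitter), flips, crop-and-resize (area fraction 0.6–1.0),
and brightness/contrast/saturation (±0.2) and hue (±0.05) distortion; all
randomness flows from an explicit seed, and a policy with all strengths
zero is the exact identity (bit-equal views).

The NT-Xent loss with temperature τ = 0.5 (the common SimCLR default) is
computed over the batch as the negative pool; no memory bank. The
projection head is a 2-layer MLP; the backbone output *before* the head is
exported as the embedding, standard SimCLR practice. Two backbones are
provided: a `resnet18-style` residual network (embed_dim 512, the
documented default for realistic use) and a `small-cnn` (8× average-pool
input, 3 conv blocks, embed_dim 64) used throughout the tests so the whole
pipeline trains in CPU minutes. Weights are randomly initialised from the
stated seed; no pretrained weights are used anywhere.

## Multi-scale splice

The spliced vector is `[v_0.5 ‖ v_2.0]`, fine scale first; the order is
fixed purely for reproducibility. No re-normalisation is applied after
concatenation — the downstream classifier learns any needed scaling.

## MIL classifier and key patches

A binary MLP (hidden 512/128, dropout 0.25) scores each spliced embedding
as lesion vs background; the 4-level grade is resolved later by the
aggregator, not here. Training is iterative max-instance MIL: each epoch
the current model ranks a bag's instances and the top `s_train` (default
1) inherit the bag's binary label; this is the canonical weak-label
propagation scheme for the "at least one positive instance" hypothesis.
Model selection uses slide-level validation error with slide score =
maximum instance probability. Top-k selection is descending by
probability with deterministic (row, col) tie-breaking; k defaults to 20,
with a config override (an alternative reading of the aggregation stage
passes 100 patches).

## Transformer aggregator

Selected key patches are projected to the model width (default 256 for
real use; 32–64 in tests), a learned class token is prepended, and 2
pre-norm self-attention layers (4 heads, GELU-free ReLU feed-forward,
dropout 0.1) pool the set. There is **no positional encoding**: the key
patches are treated as an unordered set, so the output is permutation
invariant by construction (verified to 1e-6). Short bags are padded with a
fully masked pad token; masking is exact (−1e9 pre-softmax, which
underflows to zero attention in float64). The head is a 4-way softmax
trained with cross-entropy; an ordinal alternative (expected-grade
regression through the same softmax) is available behind
`head="ordinal"` but is not the default. The binary ROC score of a slide
is P(grade 2) + P(grade 3), i.e. predicted moderate-or-marked disease.

## Staging

Compartments: antrum = {antrum lesser, antrum greater, incisura}, corpus =
{corpus lesser, corpus greater}; the incisura is grouped with the antrum
per OLGA convention. The compartment score is the arithmetic mean of site
grades rounded half-up (default), with "max" as a configurable
alternative since the original systems score compartments from multiple
fragments without a single prescribed pooling formula. Stages come from
the published 4×4 OLGA/OLGIM lattices, shipped as editable CSV data files
so the transcription is auditable; both matrices share the same lattice.
The tests assert all 16 cells of each matrix, monotonicity in each
argument, and stage 0 ⟺ both compartment scores 0.

## Metrics

AUC is the pairwise concordance probability (ties ½), computed via
scikit-learn and verified against a brute-force all-pairs oracle in the
tests; sensitivity/specificity use the fixed 0.5 cutoff with predicted
positive iff score ≥ 0.5. Weighted kappa uses |i−j|^p/(k−1)^p weights with
p = 2 (quadratic) by default, the usual choice for ordinal pathology
grades, and is verified against an explicit contingency-table oracle.
Confidence intervals are seeded percentile bootstraps (default 1000
resamples); degenerate single-class resamples are dropped. Slide-level
ROC binarizes at grade ≥ 2; patient-level ROC binarizes at stage ≥ III
(the high-risk convention).

## Synthetic data

The generator emulates the *supervision structure* of graded slides, not
their appearance. A slide of grade g plants each tile as lesion with
probability f(g) — f = (0, 0.1, 0.3, 0.6) — forcing at least one lesion
tile when g > 0. Background tiles are smooth pale-pink fields with
low-frequency mottle; lesion tiles add a high-frequency oriented stripe
pattern, a hue shift toward blue-purple, and a darkening, all scaled with
grade, so the cohort carries both an abundance signal and an intensity
signal for 4-way grading. 2.0 MPP parent tiles are exact 4× area
downsamples of the child mosaic. Cohorts follow the five-site topology
with per-site grades drawn around a patient-level latent severity; true
stages are computed through the staging module itself.

Lesion pixels are rendered from one designated feature's grade (default
atrophy); the other features' grades exist in the truth tables for
staging but do not alter pixels, so the pipeline models the designated
feature. Predicted OLGA needs only the predicted atrophy grades (the OLGA
matrix reads no other feature), so patient-level prediction is complete
for the modeled feature.

`generate_feature_bags` additionally provides embedding-space bags
(isotropic Gaussian background, lesion instances shifted 4σ along a random
direction) for exercising the MIL trainer without an encoder in the loop.
The 4σ default follows the stated precondition that lesion and background
populations be linearly separable by a small classifier; at 2σ the
instance-level overlap (AUC ≈ 0.92) defeats max-instance MIL by
construction rather than by any fault of the algorithm.

What passing tests show: the machinery — weak-label propagation, key-patch
ranking, set aggregation, staging arithmetic — recovers planted structure
exactly or near-exactly. What they do not show: performance on real H&E
slides, with stain variation, ambiguous morphology, scanner artifacts and
label noise; the perfect held-out scores on synthetic cohorts are a
property of the separable generator, not a clinical claim.

## Problem sizes and numerical choices

Test- and acceptance-scale runs use a 60-patient cohort (300 slides, 8×8
child grid → 64 tiles at 0.5 MPP and 2×2 at 2.0 MPP per slide), SimCLR
pretraining of the `small-cnn` on a 256-patch subsample for 3 epochs
(batch 32), 30 MIL epochs and 30 aggregator epochs — sizes chosen so the
full pipeline runs in a few CPU-minutes while leaving all four grades
represented in every split. Splits are patient-level (all five slides of
a patient stay together), 4:1 test then 4:1 validation, stratified by the
patient's true OLGA stage.

All arithmetic is float64 on a single thread; every stochastic component
(augmentation, initialisation, dropout, shuffling, bootstrap) draws from
an explicitly seeded generator, so same-seed reruns are bit-identical,
including the serialized manifests and the metrics JSON. Ties in top-k
selection break by (row, col); softmax and NT-Xent use max-shifted
log-sum-exp; attention masking uses −1e9 additive logits. Degenerate
inputs (empty bags, single-class training sets, missing parents or sites,
out-of-range grades, unknown config keys) raise typed errors before any
compute.

## Known limitations

- No stain normalisation, overlap tiling, or vendor WSI format support;
  the pyramidal-TIFF adapter is the only non-PNG input path.
- The resnet18-style backbone is functional but slow on CPU at scale; the
  small-cnn is the practical test backbone.
- One model per feature; there is no multi-task sharing across the four
  features.
- Heat maps render MIL patch probabilities, not transformer attention.
- The ordinal aggregator head is provided but deliberately not default;
  nothing here establishes which the original system used.
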