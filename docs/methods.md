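# Methods

## Problem setting

A 2-D B-mode renal ultrasound image shows one kidney that may exhibit
pathologies at two granularities: *global* conditions that alter the
appearance of the whole organ (hyper-echoic cortex, HC; poor
corticomedullary distinction, PCD) and *local* lesions confined to a
region (cysts, pyramids, hydronephrosis, and a long tail of rarer findings
grouped as "others"). A case may carry several concurrent pathologies, so
every categorical output in this package is multi-label: a length-(P+1)
vector of independent probabilities, index 0 reserved for "healthy",
indices [1, L] local, [L+1, P] global (defaults L = 4, G = 2, P = 6).

## Network

The three branches share a four-stage strided convolutional backbone
producing maps `T_l` at stride `2^l` with `C_l = width_base · 2^l`
channels. The default `width_base = 128` reproduces the 256/512/1024/2048
channel schedule of a ResNet-50-class encoder; the `tiny` profile
(`width_base = 4`, pyramid width 16) keeps the stride schedule but is
small enough to train on one CPU in minutes. Two feature pyramids with
independent parameters (lateral 1×1 projections, top-down nearest
up-sampling, 3×3 smoothing, fixed width C) serve the segmentation and
detection branches separately, so each task can shape its own multi-scale
representation while the backbone is shared.

* **Segmentation** — a dense head on the finest image-pyramid level emits
  per-pixel kidney logits, up-sampled to input resolution. The soft mask
  is binarized at 0.5 (boundary included); connected components act as
  instance candidates and the component with the highest peak probability
  is kept, since each image contains one kidney. No candidate above
  threshold yields an empty mask plus an explicit no-detection flag.
* **Image classification** — global average pooling of `T_4` followed by
  one linear map and per-category sigmoids. The head deliberately sees
  the full image, not a kidney RoI: global pathologies are defined by
  contrast relations between the kidney and its surroundings.
* **Detection** — a dense anchor head on the stride-4 region-pyramid
  level, two square anchor sizes (12 and 24 px) per cell, with L class
  sigmoids and 4 box offsets per anchor. Each candidate carries its
  argmax class and that class's probability; per-class greedy NMS
  (IoU 0.5) runs before the survival threshold on `s_n` (default 0.5),
  which makes the survivor set monotone in the threshold. Because a
  candidate can only be suppressed by a higher-scored one, the
  implementation discards sub-threshold candidates before NMS — provably
  the same survivor set, at a fraction of the cost.

The network is implemented on a small reverse-mode autodiff engine
(`uricads.nn`) operating on float64 numpy arrays: im2col convolutions,
nearest up-sampling, gather/concat, and numerically stable binary
cross-entropy and smooth-L1 losses. Gradients of every op are verified
against central finite differences in the test suite.

## Diagnosis generation

Region scores are aggregated per local category k over the surviving
descriptors assigned to k: max (default), mean, log-mean-exp, or
score-times-area normalized by the kidney pixel count (clamped to [0, 1],
since a box larger than the kidney could otherwise exceed 1). Mean and
log-mean-exp divide by the per-category region count so each entry stays
a probability and the ordering mean ≤ lme ≤ max holds (Jensen); a
`literal=True` flag instead divides by the total region count N across
categories, under which a sparse category's lme can leave [0, 1]. A
category with no surviving region scores 0 — no detected evidence.

The healthy entry is `p^r_0 = 1 − (1/L) Σ p^r_k` and the global entries
are zero (the region branch carries no global evidence). Fusion is the
per-category convex combination `p = α p^i + (1 − α) p^r`. Two
parameterizations of α are provided: one learned vector per model
(category-level) and a per-case linear attention layer over
`[p^i; p^r]`. The proportionality in the attention definition is resolved
as an elementwise logistic squash, which enforces α ∈ [0, 1] by
construction; the category-level α is likewise stored as logits through a
sigmoid so the constraint can never be violated during optimization.

`fit_fusion` minimizes the sum over categories of binary cross-entropy
(mean over cases) by full-batch gradient descent with backtracking line
search, so the loss trajectory is non-increasing by construction. The
attention fit is warm-started from the category solution (W = 0, b =
category logits): its training loss therefore never ends above the
category-level loss, mirroring the fact that attention strictly
generalizes a constant α.

## Training

The total loss is the unweighted sum `L_seg + L_clas + L_reg + L_dgm`:
per-pixel BCE for the mask, a sum of P+1 BCEs for the image head, anchor
BCE (positives and negatives contribute equal total weight; positives are
anchors with IoU ≥ 0.3 to a lesion plus the best anchor per lesion) plus
smooth-L1 box regression for the detector, and a sum of P+1 BCEs on the
fused vector, which trains the fusion parameters jointly with the
branches. During joint training the region vector is built from the
surviving detections with gradients routed through the selected anchor
scores (max-aggregation picks one anchor per category).

Optimization uses Adam at lr 2e-3, batch size one. Momentum SGD is
available in the config but is not the default: with four heterogeneous
loss terms at batch size one it required aggressive gradient clipping to
stay finite, and the clipping in turn stalled the classification branch;
Adam's per-parameter scaling trains all branches reliably. Each
cross-validation repetition trains on three folds, validates on one
(checkpoint selection by the mean of validation Dice and binary AUC) and
tests on one, so five repetitions test every case exactly once.
Augmentation applies rotation (±15°), gamma (0.8–1.25), translation
(±10%) and zoom (0.9–1.1), each with probability 0.5, identically to
image, polygon and boxes; a draw that ejects the kidney from the frame is
returned untouched and flagged. One master seed fans out to
initialization, shuffling and augmentation streams.

## Synthetic phantoms

The generator emulates the structure of annotated clinical cases: one
kidney ellipse per image (polygon = 48 sampled boundary points, so the
rasterized area is within a few percent of πab), a darker cortex ring
around a brighter sinus on a dark background, multiplicative Rayleigh
speckle followed by light Gaussian smoothing, and pathology recipes that
follow the qualitative echogenicity descriptions of the taxonomy: cysts
as dark uniform disks, pyramids as small dark spots at the cortex/sinus
interface, hydronephrosis as an enlarged dark sinus core, "others" as
bright foci (lithiasis-type foci cast a darkened vertical shadow band),
HC as cortex brightening, PCD as contrast collapse between cortex and
sinus. Lesion boxes are tight by construction and placed ≥ 95% inside
the kidney. Default intensities (background 0.10, cortex 0.45, sinus
0.75) and speckle strength 0.25 were chosen once so that the conditions
are clearly distinguishable at 96×96 — the phantoms target testability of
the pipeline, not physical realism. The default study mixture is 40%
healthy, 15% cyst, 10% each pyramid/hydronephrosis/others, 7.5% each
HC/PCD, one condition per image.

What passing phantom tests show: that the architecture, losses, fusion
and evaluation stack are wired correctly and can learn echogenicity
contrasts of the kind clinicians describe. What they do not show:
performance on clinical ultrasound, whose speckle statistics, anatomy
variation, probe geometry and label noise the phantoms deliberately do
not model.

## Evaluation

Per category (one-vs-rest): the area under the sensitivity–specificity
ROC, computed as the Mann–Whitney statistic with ties credited 0.5, and
the maximum specificity among thresholds whose sensitivity reaches 95%
on the empirical step ROC (no interpolation) — the triage reading is the
fraction of healthy cases correctly not referred under a 95% referral
guarantee for pathological ones. Scores are pooled across test folds by
default (a per-fold macro option exists); categories with single-class
pooled labels are excluded from averages with a warning. Segmentation is
scored with IoU and Dice (both-empty pairs defined as 1); the identity
Dice = 2·IoU/(1+IoU) is asserted per pair in the tests.

## Problem sizes and numerical choices

The end-to-end study trains the tiny profile on 200 phantoms at 96×96
(170 train / 30 validation) for 12 epochs and evaluates on 50 held-out
phantoms — about 80 seconds on one CPU. Box coordinates are half-open
`[x_min, x_max) × [y_min, y_max)` in 0-based pixels; rasterization sets a
pixel iff its center `(c+0.5, r+0.5)` is inside the polygon under the
even-odd rule; degenerate polygons rasterize to an empty mask with a
warning. Detection box deltas clamp `exp` arguments to ±4. Probabilities
entering logarithms are clamped at 1e-7. Grayscale inputs are replicated
to three channels; image sides must be ≥ 32 and divisible by 16 so the
stride schedule and the ×2 mask up-sampling close exactly.

## Known limitations

The segmentation and detection branches are compact dense heads rather
than full two-stage RoI architectures; they honor the same input/output
contracts but at clinical scale a pretrained two-stage detector would be
the stronger choice. Joint training supports max-aggregation only (other
aggregations remain available for post-hoc fusion fitting). Phantoms
contain exactly one condition per image, so correlations between
concurrent pathologies are not represented in the synthetic study.
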