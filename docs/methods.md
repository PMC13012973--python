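# Methods

## The problem

Bone age assessment (BAA) reads skeletal maturity, in months, from a hand/wrist
radiograph. In the Greulich–Pyle (GP) method the radiograph is matched to the
closest standard in a reference atlas, so every GP age is a member of a
discrete, sex-specific grid of ages `G`. Maturation is not uniform across the
hand: tubular bones (metacarpals, phalanges, radius, ulna) respond mainly to
sex steroids while the carpals follow a different trajectory. This package
models that asynchrony by grouping the hand into three segments with coherent
within-group maturation — **short bones** (metacarpals + phalanges),
**carpals**, and **wrist** (distal radius + ulna) — training one age regressor
per segment plus one for the full hand, and fusing their outputs.

## The segmental GP (SGP) estimate

Let `fh_i` be the full-hand prediction for image `i` and `Seg_Avg_i` the
arithmetic mean of the three segment predictions. The fused estimate is the
convex combination

    C_i = α · Seg_Avg_i + (1 − α) · fh_i,        α ∈ [0, 1],

snapped to the closest GP class, `C̃_i = argmin_{g∈G} |C_i − g|`. The per-sex
weight `α*` minimizes `Σ_i (C̃_i − y_i)²` where `y_i` is the full-hand GP
ground truth; because the snapped loss is piecewise constant in α, the minimum
is found by an exhaustive sweep of `[0, 1]` (default grid step 0.01, matching
the two-decimal precision at which such weights are usually reported), with
plateau ties resolved toward the smallest α. Inference reports
`SGP_i = snap(α*·Seg_Avg_i + (1−α*)·fh_i)`, always a member of `G`. Snapping
ties at exact midpoints go to the lower (younger) class — a conservative
choice. By construction the fitted `α*` can never do worse, in summed squared
snapped error on the fitting split, than the full-hand-only (`α=0`) or
segment-average-only (`α=1`) endpoints. Fitting is strictly per sex; applying
a male fusion model to female records is an error. The sweep is evaluated on
the validation split by default (`fit_alpha` simply takes whatever records it
is given, so either split can be supplied).

The GP grid itself ships as an editable CSV (`sex,age_months`); the built-in
default is an illustrative grid spanning 12–228 months (male) / 12–216 months
(female) with denser classes around puberty, not the clinical atlas list.

## Synthetic phantoms

Real cohorts (and their labels) are not required anywhere: a phantom generator
produces radiograph-like images in which each segment carries its own,
independently controllable maturity signal, with exact ground-truth masks:

* short bones — four elongated bars, each interrupted by two epiphyseal gaps
  whose width shrinks linearly to fusion as shortbone age runs over the grid;
* carpals — seven circular ossification centres whose radius (hence total
  ossified area) grows with carpal age and saturates at 85 % of the grid range
  (carpals are fully ossified after puberty and lose discriminative power);
* wrist — two thick bars (radius, ulna) with one epiphyseal gap that narrows
  with wrist age.

Geometry is a fixed layout table; only additive Gaussian texture noise
(default sd 0.02 in [0,1] intensity units) and a small sub-pixel jitter of
structure centres are random, and the jitter is drawn from the seed before
any age enters, so age sweeps at a fixed seed are strictly comparable. Latent
ages are continuous and uniform over the grid range; labels are snapped to
`G`, mirroring discrete clinician labels over continuous maturity. Segment
asynchrony is a Gaussian offset per segment (default sd 9 months) added to
the full-hand age before snapping. Sex changes only the GP grid and a global
size factor (0.96 for female phantoms).

Domain shift is modelled as the global intensity/contrast map
`clip(gain·x^gamma + offset, 0, 1)` — an emulation of a scanner/protocol
change, not a fit to any real cohort. What the phantoms deliberately do *not*
model: soft tissue, individual carpal identities, projection geometry,
left/right standardization, or any real radiographic texture. Tests passing on
phantoms therefore validate the pipeline's mechanics (segmentation, transfer,
fusion, metrics), not clinical accuracy.

## Synthetic prediction tables

The fusion stage is additionally exercised on tables with a *known* generative
weight `α0`. The generator first draws the combined estimate
`combo = latent + ε`, `ε ~ N(0, noise_sd_fh)`, then splits it into a
disagreeing pair

    fh      = combo − α0 · δ,
    Seg_Avg = combo + (1 − α0) · δ,      δ ~ N(0, disagreement_sd),

so that `α·Seg_Avg + (1−α)·fh = combo + (α − α0)·δ` and the expected loss is
minimized exactly at `α0` whatever the noise levels — this is what makes `α0`
recoverable by the sweep. The three segment predictions scatter around
`Seg_Avg` with mean-centred noise (sd `noise_sd_seg`), leaving the average
untouched. `disagreement_sd` defaults to twice the larger noise sd, so the
noiseless case degenerates to `fh = Seg_Avg = latent`.

## Segmentation and test-time adaptation

A small two-level encoder–decoder (channels 8/16/32, 3×3 convolutions,
skip connections, ~40k parameters) predicts the three mask channels at 64×64
from the grayscale image, trained with positive-weighted binary cross-entropy
(weight = √(background/foreground) per channel; thin finger bones are a few
pixels wide and an unweighted loss occasionally lets that channel collapse to
all-background). The network is built on a small NumPy layer library inside
the package (im2col convolutions, channel normalization, Adam); convolutions
pad by edge replication so a constant image maps to a constant per-channel
response.

Normalization layers support three statistic modes:

* `train` — per-sample (instance) statistics; running buffers accumulate their
  batch averages;
* `eval` — the stored running statistics (`tta=false`);
* `adapt` — statistics recomputed from the current input only, with no
  parameter or buffer updates (`tta=true`).

Because the first normalization directly follows a linear convolution with
constant-preserving padding, `adapt`-mode thresholded masks are invariant to
positive affine intensity transforms of the input (`x → a·x + b`, `a>0`) up to
floating point, and `adapt` inference sees exactly the normalization used in
training. `eval` mode, by contrast, carries the source-domain statistics and
degrades sharply under intensity shift — the failure mode that test-time
adaptation exists to fix, and the package reproduces that contrast on the
phantom shift suite.

Raw masks are refined classically: morphological opening/closing (configurable
radii), connected components, drop components below an area threshold
(default 0.1 % of image area) or whose mean underlying intensity is below
0.15, keep the `keep_top_k` largest, and resolve overlaps between segments in
favour of the larger component. The library default `keep_top_k=1` suits
single-blob ROIs; the pipeline overrides it to 12 (and disables opening)
because phantom segments are legitimately multi-component at 64×64 — finger
pieces separated by open gaps, seven carpal centres, two wrist bars. Refined
masks drive tight, letterboxed 64×64 crops with everything outside the mask
set to exactly 0. Coordinates are row-major and 0-based; boxes half-open.

## Age regression and same-domain transfer

Each (sex, segment) regressor is a three-block CNN (Conv–norm–ReLU–pool,
8/16/32 channels, global average pooling, linear head) on 64×64 inputs —
small enough to train on one CPU in seconds; a heavier backbone can be swapped
in via `build_backbone`. Inputs are normalized by the mean/sd of the
*training* images; labels are standardized internally (the head regresses
z-scores, restored to months at prediction). Training minimizes L1 loss
(directly the MAD) with Adam (default lr 1e-2, 30 epochs, batch 8); after SGD
the running normalization buffers are re-estimated with one full-data pass and
the head is re-solved in closed form on eval-mode features, aligning inference
with training. Predictions are clamped to [0, 300] months for physical
plausibility.

Transfer to a shifted target cohort freezes everything except the final
linear head, which is re-fit by ridge-regularized least squares (λ=1e-3, no
shrinkage on the intercept) on the frozen pooled features of target images —
deterministic, exact, and byte-preserving for every non-head parameter.
Target inputs are normalized with the *source* statistics, preserving the
distribution the frozen features were trained on. When two raters label the
target cohort, the training label is their arithmetic mean (`average_raters`);
models train on the raw mean and snap only at evaluation/fusion time.

## Agreement statistics

* MAD `mean|pred−truth|` and RMSE, in months.
* `r²` is the squared Pearson correlation (what a correlation plot shows),
  *not* the regression coefficient of determination — they differ for biased
  predictors; both the continuous and the snapped-prediction variants are
  reported because it is ambiguous which one a plot of discrete classes shows.
* Bland–Altman: differences `d = pred − truth` (positive bias =
  overprediction; stated in every report), bias = mean(d), limits
  bias ± 2·sd(d) with the sample (n−1) sd — exactly 2, not 1.96, configurable —
  and cases strictly outside the limits flagged as high-error.
* Quadratic-weighted Cohen's κ over *grid indices* (not raw months), so
  unequal class spacing does not distort the weights; plus exact and
  within-±k-class agreement percentages.

Every statistic is verified in the tests against an independent brute-force
loop implementation, and κ additionally against scikit-learn.

## The end-to-end pipeline

`run_pipeline` executes the whole study at desk scale: simulate source and
shifted target cohorts per sex → train the segmenter on source phantoms →
train base regressors (segment models on ground-truth-mask crops) → transfer
heads on target crops obtained from the segmenter with TTA + refinement (with
per-segment fallback to the raw mask, then the whole image, each recorded as a
warning) → predict on the target validation split → fit α* per sex → write
SGP, full-hand and per-segment agreement reports plus a manifest (config,
config hash, seed, artifact paths, report summaries). All randomness flows
from one root seed through named substreams, so reports are byte-identical
across reruns in single-threaded mode; timing appears only in the log.

Default problem sizes are deliberately small so a full run takes well under a
minute on one CPU: 40 phantoms per sex (60/40 train/validation split) at
96 px, a 10-epoch segmenter at 64 px, 25-epoch regressors. These sizes are the
package's study conditions; at this scale per-image MADs are of order 10
months rather than the ~5 months achievable with large cohorts and deep
backbones, but the qualitative structure is stable across seeds: the full-hand
model beats every single-segment model, the carpal model is the weakest
segment, and the fused SGP estimate beats the full-hand model.

## Known limitations

* Phantoms are geometric caricatures; no claim transfers to real radiographs
  without retraining and clinical validation.
* The NumPy networks are CPU-bound and small; the DenseNet-scale backbones
  used in production BAA systems are out of scope (pluggable, not shipped).
* α is a single per-sex constant; age-adaptive weighting is deliberately not
  implemented.
* κ confidence intervals and Bland–Altman trend tests are not provided.
* DICOM import is a convenience conversion (percentile windowing to 8-bit
  PNG); the pipeline proper speaks PNG + CSV only.
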