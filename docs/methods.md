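# Methods

## HRLG enhancement

The enhancement stage treats low contrast in a brain slice like atmospheric
haze in a natural image.  Under the haze model `C(x) = γ(x) t(x) + A (1 − t(x))`,
the dark-channel prior (in haze-free patches some channel is near zero)
yields the transmission estimate `t = 1 − ω · dark(C / A)`; the radiance is
recovered per channel as `γ = (C − A) / max(t, t₀) + A`, then re-contrasted:

* global map `G = (1 + g_k)(γ − k_mean) + σ`, where `k_mean` and `σ` are the
  mean and **population** (1/N) standard deviation of the radiance over all
  pixels and channels.  The population convention is used consistently in the
  implementation and its oracle tests.  A constant image maps to zero.
* local map `H = sd_w(γ) + φ·μ`, with `sd_w` the windowed standard deviation
  (edge-replicated) and `μ` the **global scalar mean** of the dehazed image.
  `μ` is written with pixel indices in some formulations but described as the
  image mean; the scalar reading is implemented because a per-pixel `μ(x,y)`
  would collapse `H` to `sd + φ·γ`, double-counting the radiance.
* fusion `Y = clip(G + H − I, 0, 1)` against the original image `I`.

Parameters (all exposed via `DehazeParams` / `ContrastParams` and YAML):

| parameter | default | meaning |
|---|---|---|
| `patch_size` | 15 px | dark-channel minimum window (standard prior practice) |
| `omega` | 0.95 | haze retention; 1 removes all estimated haze |
| `t0` | 0.1 | transmission floor preventing division blow-up |
| `light_fraction` | 0.001 | brightest dark-channel fraction averaged for `A` |
| `gain_k` | 1.0 | global contrast gain (doubles centred contrast) |
| `phi` | 0.2 | weight of the mean offset in the local map |
| `local_window` | 7 px | window of the local standard deviation |

The atmospheric-light estimator (mean over the top `light_fraction` quantile
of dark-channel pixels, stable tie-break by flat index) is standard
dark-channel practice; the haze model itself does not prescribe one.  Images
are floats in [0, 1]; grayscale sources are replicated to three channels so
the colour formulation applies unchanged; 8-bit quantisation happens only on
save (round-half-even).  Every windowed operator replicates edges.  The whole
stage is deterministic.

## Generalized self-attention

Given a feature map `Z ∈ ℝ^{H×W×C}`, each head projects `Z` with 1×1
convolutions to a bottleneck of `C′ = max(1, ⌊C/8⌋)` channels: the query is
globally average-pooled to a `1×C′` vector, keys and values stay `HW×C′`
(row-major flattening, `r = yW + x`).  Spatial weights are
`Z′ = softmax(Q Kᵀ)` — **no** `1/√d` temperature is applied, deliberately
departing from scaled dot-product attention to keep the published form of
the block.  The channel path aggregates values with `Z′`, expands `C′ → C`
by a biased 1×1 convolution, and gates channels through a sigmoid.  The two
reweighted maps fuse as `w₁ Z_sp + w₂ Z_ch` (scalars initialised to 0.5);
`h = 4` independent heads (independent parameters make the concatenation
meaningful; parameter-shared heads would be redundant) are concatenated and
projected `hC → C`.

The block is linear in `w₁, w₂`, so their gradients are computed in closed
form (`fusion_scalar_gradients`); a finite-difference check agrees to ~1e-10
relative error.  Projections are fan-in-scaled normal draws behind a single
seed; biases start at zero, so a zero input yields a zero output at
initialisation.

## Backbone and fine-tuning

The `tiny_test` backbone is a three-layer stride-2 3×3 convolutional stack
(3→16→32→32 channels, ReLU, He-initialised from a seed) producing a feature
map at 1/8 resolution — an 8×8×32 map for a 64×64 input.  It is a genuine,
self-contained extractor for synthetic-data runs, not a pretrained network;
the `inception_v3` option (299×299 input, final 8×8×2048 activation map)
requires pretrained weights and fails with an actionable message when they
cannot be loaded.

Fine-tuning is two-stage by design: the backbone and attention projections
stay frozen; Adam updates the dense softmax head and the per-head fusion
scalars on cross-entropy (their gradients are exact because the pooled
feature vector is linear in them — the per-image path contributions are
precomputed once, making epochs cheap).  Adam is used rather than plain SGD
because at the default learning rate of 1e-4 it converges within a few
epochs on the fixtures.  The ELM is then fitted on the pooled training
features; the softmax head exists only to give the fusion scalars a training
signal before the closed-form classifier takes over.

## Extreme learning machine

Hidden weights and biases are drawn once from `Uniform(−1, 1)` (seeded) and
never trained; `H = t(Xw + b)` with logistic-sigmoid `t` by default; output
weights solve `min‖Hα − O‖` for one-hot targets via `lstsq` (minimum-norm
solution on rank deficiency), matching an independent pseudo-inverse oracle
to 1e-8.  The fit refuses `n_hidden ≥ n_samples`: with at least as many
hidden nodes as samples the system can interpolate noise exactly, which is
why exact "zero-error" output is impossible in the admissible regime and the
least-squares reading is the only consistent one.  Prediction is the argmax
of `Hα` with ties to the lowest class index.

## Data pipeline

Balancing follows the ADNI-style plan: classes above the 500-image cap are
subsampled uniformly without replacement (seeded per class), and small
classes are expanded to an explicit target — the shipped plan triples a
144-image class to 432.  The augmentation op set is rotations
{90°, 180°, 270°, ±10°}, scales {0.9, 1.1} (centre-crop/pad back), and
horizontal/vertical flips, applied by seeded round-robin over shuffled
sources so reruns are bit-identical and each augmented file name encodes its
source and operation.  Identity operations are excluded, so every augmented
image differs from its source.  Splits are stratified 80/20 with a per-class
seeded permutation.  Augmentation precedes the split in the default flow;
isolating augmented images from evaluation is the caller's choice (run the
plan on the training manifest only).

### Phantom generator

Each phantom is a 64×64 grayscale slice: an elliptical head (≈0.42H×0.36W
semi-axes) over a dark background, smooth Gaussian-field tissue texture,
a bright cortical rim whose thickness falls from 8% to 3% of the head radius
with grade, a central dark ventricle whose semi-axes grow linearly with
grade severity (`0.05+0.10s` by `0.04+0.08s` of the image size), interior
intensity falling from 0.75 to 0.50, and additive Gaussian noise
(σ = 0.02).  Per-image jitter: ±3% head axes, ±5% ventricle axes, ~1% centre
shift.  Grades are therefore separable by construction — the per-class
intervals of mean interior intensity are disjoint.

What the phantoms do **not** emulate: anatomical variability across
subjects, scanner/protocol differences, bias fields, partial-volume effects,
registration error, or the weak and overlapping effect sizes of real
dementia grading.  A pipeline that scores highly on phantoms demonstrates
that its machinery (enhancement, attention, classifier, bookkeeping) is
correct and deterministic — not that it would reach comparable accuracy on
clinical data.

## Evaluation

Per-class one-vs-rest precision/recall/F1 (scikit-learn), accuracy as the
confusion-matrix trace fraction, and one-vs-rest ROC AUC from the ELM
decision values.  Macro averages are unweighted class means; weighted
averages are support-weighted — both are reported for AUC as well, since the
averaging convention is otherwise ambiguous.  Zero-division policy: a rate
with an empty denominator reports 0 with a logged warning; an undefined AUC
(empty or full support, or missing scores) serialises as JSON null.
Support-weighted recall equals overall accuracy by identity, which the tests
assert.

## Pipeline defaults and problem sizes

A single global seed derives every stage's sub-seed by SHA-256 hashing of
the stage name, so inserting a stage never shifts another's randomness.
HRLG enhancement is **on** by default in the training flow (`--no-enhance`
disables it); on phantoms it slightly sharpens class contrast, and the
published flow places enhancement before feature extraction.  Enhancement
runs at native resolution before any backbone resize.  The standard
synthetic run uses 5 classes × 100 phantoms, the `tiny_test` backbone, 4
attention heads, 5 fine-tuning epochs and a 100-node ELM (capped at
`n_train − 1`), completing in seconds on one CPU; test macro-F1 lands around
0.85–0.95 depending on seed, and disabling the attention block changes it
by only a few points on this easy geometry — the ablation test asserts
ordering, not a margin.

## Known limitations

* No pretrained backbone can be bundled, so parity with published
  full-scale results on restricted clinical datasets is out of scope here.
* The attention projections are not trained (only the fusion scalars and
  head are), a deliberate freeze that keeps gradients exact and cheap.
* No transmission-map refinement (e.g. guided filtering) in the dehazer, no
  volumetric (DICOM/NIfTI) handling, and no skull-stripping/registration.
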