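# Methods

`fxcallus` analyses longitudinal micro-CT of healing fractures in three
stages: lesion segmentation, bone morphometry of the segmented lesion, and
classification of the healing trajectory (union vs non-union). Because the
rat dataset the pipeline was designed around is not public, every stage is
developed and verified against a synthetic phantom generator that encodes the
study conditions. This note records the models, the defaults and why, and
what the synthetic results do and do not establish.

## Segmentation model

The segmenter is a U-shaped encoder-decoder whose mixing blocks are
vision state-space (Mamba-style selective-scan) units rather than
convolutions or attention:

* **SS2D mixer.** The feature map is unfolded into four 1-D sequences
  (row-major, column-major, and their reverses). Each sequence passes
  through an input-dependent linear state-space recurrence, discretized per
  step by zero-order hold:
  `h_t = exp(Δ_t A) h_{t-1} + Δ_t B_t x_t`, `y_t = ⟨C_t, h_t⟩ + D x_t`,
  where `Δ_t`, `B_t`, `C_t` are data-dependent projections, `A` is a fixed
  negative-definite diagonal initialized at `-1..-N` per channel (S4D-real
  style) and `Δ` is initialized so `softplus(Δ-bias)` spans `[1e-3, 1e-1]`.
  The four directional results are folded back, summed, layer-normalized and
  gated by a SiLU pathway. The scan is implemented as a single graph node
  with an analytic reverse pass (the recurrence is replayed backwards), so
  the sequential loop runs once per direction in each direction.
* **Triplet attention.** After each SS2D, three branches each swap one axis
  pair with the channel axis, Z-pool (concatenated max and mean) over the
  leading axis, convolve with a single k×k kernel (default k=7, must be odd)
  and gate the permuted input with a sigmoid; branch outputs are averaged.
  Each branch's output is elementwise bounded by the input (gate in (0,1));
  the average of three branches is not, which is why the bound is asserted
  per branch.
* **Stages.** A patch embedding (default 4×4) is followed by four encoder
  stages (default widths 32/64/128/256, two blocks each) with 2×2 patch
  merging between stages, and a mirrored decoder with patch expanding and
  additive skip connections. Inputs must be divisible by
  `patch_size · 2^(n_stages-1)`; the forward pass rejects anything else.
  The default widths are deliberately modest: the architecture is the object
  of study, and CPU-scale training keeps the whole pipeline verifiable.
* **Edge feature decoupling (EFDM).** After every decoder hidden layer, three
  supervised branches decouple what the features must preserve: an
  edge-guided module (parallel atrous convolutions, default rates 1/2/4/8,
  fused to a 1-channel edge probability), a noise-suppression head and a
  texture-preservation head (conv–norm–ReLU each, emitting scalar maps).
  When refinement is enabled the edge pathway is added back to the features
  and the noise pathway subtracted — the published description says the
  module "decouples" features but not how they recombine, so the rule is
  isolated in one place and switchable. Config flags materialize the
  ablation lattice (no branches / +edge / +edge+noise / all three) and a
  plain VSS baseline (attention and EFDM off).

**Autodiff backend.** No deep-learning framework is assumed: the network
runs on a small reverse-mode autodiff engine over NumPy (`fxcallus.nn`) with
float64 arithmetic, im2col convolutions, and hand-derived backward passes
for the convolution and the selective scan. Gradients of every operation are
verified against central finite differences in the test suite.

## Training objective

The loss sums deep-supervision terms over the M decoder stages plus a
segmentation term:

```
L_total = Σ_j L_noise_j + Σ_j L_texture_j + Σ_j L_edge_j + δ·L_seg
L_edge  = α·L_focal + (1−α)·L_dice
L_seg   = λ_bce·L_bce + λ_dice·L_dice
```

All components consume probabilities clamped to `[1e-7, 1−1e-7]`; the Dice
loss uses ε = 1e-6 in numerator and denominator. Defaults: λ_bce = λ_dice = 1
(the reference setting), α = 0.5, δ = 1, focal γ = 2 — the last three are not
specified by the source study and are package defaults. Two numerical
choices:

* the noise/texture L1 terms are **mean-normalized per map** — raw sums
  would weight pyramid stages by their pixel counts;
* "weighted dice" inside the edge loss is read as the (1−α) weighting, not a
  per-class weight.

Auxiliary targets are resampled to each stage's resolution by block-max
(binary edges — nearest-neighbour can delete a 1-pixel boundary) and
block-mean (scalar maps).

Training defaults follow the reference recipe: Adam, learning rate 1e-5,
batch size 16, best-validation-DSC checkpointing, subject-level (never
slice-level) train/val/test splits. The overfit verification uses a
reduced-width configuration (8/16/32/64, depth 1) and a smoke learning rate
of 1e-3 for ≤200 steps; at 1e-5 the same run converges too slowly to be a
useful health check.

## Evaluation metrics

DSC is `2|A∩B|/(|A|+|B|)`, defined as 1 when both masks are empty and 0 when
exactly one is. Hausdorff distances are computed between **boundary pixels**
(mask minus its erosion) in physical units; HD is the max of the two directed
maxima, and HD95 is the **max of the two directed 95th percentiles** with
linear-interpolation percentiles — the percentile convention is pinned so
numbers are bit-reproducible. HD on an empty mask is an error; batch reports
record such slices as missing rather than imputing a value. Interval
estimates everywhere are seeded percentile bootstraps (1000 resamples by
default); the bootstrap is this package's choice of interval.

The dual-annotator gate accepts either annotation only when DSC **strictly
exceeds** 0.95; a pair at exactly 0.95 goes to consensus.

## Morphometry

Within the lesion ROI, voxels are classified by HU windows: hematoma
[0, 225), cartilage [225, 331), mineralized cartilage [331, 701), osteogenic
[701, 1000]. The half-open real-valued partition resolves what integer
window bounds leave ambiguous for non-integer HU; in-ROI voxels below 0 or
above 1000 HU stay unclassified. Per tissue: BV = voxel count · voxel³; TV
sums BV over the four tissues; **BS is the mean per-slice tissue area (mm²)
over slices containing any classified voxel** and TS sums BS. BS/TS and
BV/TV are percentages, BS/TV is mm⁻¹. With a per-image pixel count alone
BS/TV cannot carry mm⁻¹; the mean-slice-area convention is this package's
explicit, deterministic choice, and TS/TV denominators include only
classified tissue — which is exactly what makes the four BS/TS and BV/TV
shares sum to 100%.

## Phantom generator

Each synthetic scan is a tubular bone cross-section — cortical shell at
1500 HU around a trabecular interior at 1100 HU, soft-tissue background at
−100 HU — cut by a 1 mm-wide rectangular notch from the outer margin to the
bone centre, replicated across slices. The default rendering uses 0.04 mm
voxels on 64×64 slices (a 4× coarser grid than the 10 µm acquisition it
emulates) so the ~2 mm bone and 1 mm notch fit a CPU-scale image.

Inside the ROI, a per-(group, day) composition table fixes the shares of the
four tissue classes plus an **unclassified gap fraction** (soft tissue in the
unbridged lesion). Voxels are layered by distance to intact bone —
osteogenic closest, then mineralized cartilage, cartilage, hematoma, gap at
the core — mimicking callus maturation from the fracture edges inward. HU
values are drawn from per-tissue truncated Gaussians held strictly inside
each window, so at zero added noise the window classifier reproduces the
generating map exactly; optional Gaussian imaging noise is added on top.

Default compositions follow the measured group/day BV/TV shares of the rat
study (normalized over the four tissues), and tissue HU means/SDs follow its
measured average CT values. The gap trajectory encodes the healing contrast:
fracture-only (F) shrinks from 60% (day 1) to 5% (day 35); the
artery-transected group (F+S) stays near 45–60% throughout. This is the
package's construction: the classified-tissue shares alone cannot express
bridged-vs-unbridged (they are normalized to classified voxels), so the gap
dimension carries it, and the day-35 in-ROI osteogenic fraction comes out
~0.51 (F) vs ~0.32 (F+S) — the healed/non-healed direction.

Auxiliary supervision maps are a pinned, reproducible construction (the
source study never defines how its noise/texture ground truths were made):
edge = the ROI's one-pixel inner boundary; noise = |image − 3×3 median|
restricted to a 5-pixel band around the ROI; texture = 5×5 local standard
deviation of the median-filtered image inside the ROI; the scalar maps are
max-rescaled to [0, 1] per slice (a `normalize` switch exposes the raw
residuals, whose mean grows monotonically with the injected noise level —
the rescaled maps are scale-free by design).

Sampled feature tables draw the ten diagnosis indices from per-(group, day)
Gaussians with the study's means/SDs, truncated at physical bounds: HU in
[0, 1000], percentages in [0, 100], ratios ≥ 0. Average-CT features are
truncated to the full classified range rather than each tissue's own window
because measured tissue means can fall outside their window (partial-volume
averaging in the reference data does exactly this); window truncation would
bias the sampler away from the tabulated statistics.

**What the phantom does not emulate:** anatomically realistic geometry,
beam hardening, ring artifacts, partial-volume voxels at tissue interfaces,
intra-tissue spatial correlation, or inter-slice anatomy changes. Passing
tests therefore establish correctness of the algorithms under the encoded
composition model, not segmentation or diagnosis performance on real scans.

## Diagnosis harness

Ten indices per sample: avg CT of hematoma and cartilage, BS/TS of all four
tissues, BS/TV of mineralized cartilage and osteogenic tissue, and BV/TV of
osteogenic tissue; the published list enumerates nine while announcing ten,
so BV/TV of mineralized cartilage is included as the tenth behind a switch
(`include_tenth_index`) — it is the only remaining index with a clear group
contrast, but the attribution is this package's guess. Day-1 rows are
dropped by default (post-surgical variation dominates).

Classifiers: RBF-kernel SVM, MLP (one hidden layer of 32), decision tree,
random forest (100 trees) — scikit-learn defaults otherwise, pinned in the
report for reproducibility since the source gives no hyperparameters.
Five-fold cross-validation is **subject-grouped by default** (no subject in
two folds — leakage-safe when multiple samples share a subject), with
`group_folds=False` available for plain stratified folds.
Standardization statistics come from each training fold only. Out-of-fold
scores are pooled; AUC is the tie-corrected Mann–Whitney statistic; accuracy,
precision and F1 are recomputed from the pooled confusion counts; intervals
are seeded sample-level bootstraps.

## Problem sizes used in verification

The shipped verification runs use: 16³ random volumes (50) for the
morphometry oracle; ≤50-point boundary sets (200) and ≤60-score vectors
(100) for the metric oracles; a 4-slice 64×64 phantom with the reduced-width
network and ≤200 Adam steps for the overfit check; 20-seed phantom batches
for composition recovery; and 100 samples per group × 10 seeds for the
day-14 diagnosis recovery. These sizes make the whole verification suite
run in a few minutes on one CPU while keeping every check statistically
meaningful.

## Known limitations

* The selective scan is a sequential NumPy loop: fine at desk scale,
  unsuitable for full-resolution (≈650-slice, 10 µm) training.
* BS (and hence BS/TV) depends on the slice-aggregation convention described
  above; values are not comparable to tools that use stereological surface
  estimates.
* The phantom's composition model treats tissue shares as spatially layered
  deterministic fractions; real calluses interleave tissues.
* Confidence intervals are percentile bootstraps over slices/samples and do
  not model subject-level clustering in the segmentation report.
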