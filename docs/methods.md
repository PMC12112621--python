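# Methods

This note documents the models, default parameters, numerical choices
and known limitations of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic smear generator

The generator exists to give every downstream stage pixel-exact ground
truth. Each cell is a polar boundary function
r(θ) = r_ellipse(θ) · (1 + Σ aᵢ cos(fᵢθ + φᵢ) − Σ notches), rendered with
a ~1-px anti-aliasing ramp; the stored mask is the α ≥ 0.5 level set,
boxes are the tight boxes of masks, and the background is seeded smooth
texture plus per-pixel Gaussian noise (σ = 0.012).

Default study conditions (sampled per cell, µm):

| archetype | defining render | key measured property |
|---|---|---|
| Normal | disc d 6.8–7.6, round pallor (radial fraction 0.40–0.50) | circ > 0.9, d 6–8 |
| Macrocyte | disc d 9.6–10.6 | d > 8.5 |
| Microcircle | disc d 4.8–5.5 | d < 6, circ > 0.9 |
| Oval | ellipse ecc 0.41–0.47 (area-preserving) | 0.35 < e ≤ 0.5 |
| Elliptocyte | ellipse ecc 0.64–0.72 | e > 0.5 |
| Pencil | aspect 3.3–3.8, no pallor | e > 0.85, AR > 3 |
| Stomatocyte | ripple freq 10+13 amp ~0.085, slit pallor | circ < 0.7, pallor ecc > 0.7 |
| Target | dark center spot, pallor annulus, dark rim | ≥ 2 radial inversions |
| Spleen | disc, uniform rim color (no pallor) | pallor absent, circ > 0.9 |
| Hyperchromasia | disc, uniformly dark interior | interior luminance < 0.45 |
| Howell-Jolly | disc + one mid-radius dark blob (~1.2 µm) | exactly 1 inclusion |
| Heinz bodies | disc + rim-touching dark blob | peripheral inclusion |
| Hemoglobin-C | disc + central dark bar 3.6 × 0.76 µm | inclusion ecc > 0.8 |
| Fragments | d 4.6–5.4 base with three deep notches | area < ½ normal, solidity < 0.85 |
| Pikilocyte | ripple freqs 3/6/9 amp 0.12–0.17, normal pallor | matches no other rule |

Two geometry facts shaped the ripple choices. First, boundary ripple
pairs whose frequencies differ by 2 couple into a quadrupole and inflate
the moment eccentricity; the irregular-cell ripples use frequencies
(3, 6, 9) so lumpy cells keep e well below the Oval band. Second, deep
angular notches reduce solidity much more effectively than shallow wide
ones at 40–50 px cell diameters; fragments use three Gaussian notches of
depth 0.72–0.8.

What the generator does **not** emulate: stain variability, optics/PSF,
cell crowding and rouleaux, debris, illumination gradients, focus
errors. Passing tests therefore certify the measurement and rule
machinery on idealized geometry, not performance on clinical images.

Augmentation uses nearest-neighbor resampling (so flip/0°-rotation
identities are exact), rotation limited to ±15° and shear to ±0.2 rad;
boxes are recomputed from the transformed masks and a cell is dropped
when less than 20% of its mask survives the transform. Deduplication is
difference-hash (8×8 gradient signs) with default distance threshold 0
(exact hash duplicates); rebalancing oversamples a deficient class by
seeded crop-duplication plus a random flip/rotation so per-class counts
hit targets exactly. Per-channel min–max normalization raises on a
constant channel rather than emitting zeros.

## Morphometry

The 50-descriptor registry is the single source of truth for names,
order, units and groups (geometric 20, nuclear/cytoplasmic 10, texture
8, color 6, specialized 6). The enumeration from prose to exactly 50
entries is necessarily interpretive; the two filler nuclear descriptors
are `nuclear_solidity` and `nuclear_displacement` (nucleus-centroid
offset over equivalent cell radius).

Numerical choices:

* Axes/orientation/eccentricity from central second moments of the mask
  (rotation-equivariant).
* Perimeter: marching-squares contour, lightly smoothed with a circular
  moving average (window 5) before summing segment lengths. The raw
  staircase polygon overestimates a disc's perimeter by ~5%, which would
  push circularity of an ideal disc below 0.9; after smoothing a
  rasterized r = 40 px circle measures circularity within [0.92, 1.02].
* Texture: gray-level co-occurrence at distance 1, four angles,
  32 levels quantized within the mask; pairs touching the outside-mask
  level are discarded before normalization, so a flat interior measures
  entropy 0 / energy 1 / contrast 0 exactly.
* Minimum Feret diameter by convex-hull caliper widths.
* Volumes as prolate spheroids of the moment ellipse.
* Specialized metrics: granularity = Laplacian variance over cytoplasm;
  vacuolation = bright-blob area fraction of cytoplasm; inclusion
  presence = dark blobs (≥ 2 px, luminance < median − 0.25) inside the
  cell; membrane integrity = fraction of boundary pixels with gradient
  magnitude above 0.05; cytoplasmic granularity = co-occurrence energy
  over cytoplasm; lobe count = nucleus components after one erosion.
* Automatic nucleus segmentation (when no mask is given): Otsu on blue
  absorbance within the cell, rejected unless the split separates means
  by ≥ 0.15 — anuclear cells return an empty nucleus.

Rule-engine evidence that is not a registry descriptor (central-pallor
area fraction and eccentricity, inclusion blob statistics, radial
intensity inversions, mean interior luminance) travels in
`MorphometryVector.extras`. The radial profile is computed over
distance-transform depth bins; "inversions" are counted on the mirrored
rim→center→rim profile by a hysteresis turning-point scan with
prominence 0.06, which is robust to plateaus and pixel noise (a normal
disc scores 1 — the central pallor maximum; a target form scores 3).

## Anomaly rules

Priorities (0 fires first): Hemoglobin-C, Heinz, Howell-Jolly, Target,
Fragments, Macrocyte, Microcircle, Pencil, Elliptocyte, Oval,
Stomatocyte, Hyperchromasia, Spleen, Normal, Pikilocyte (catch-all).
All thresholds live in `RuleConfig` and are strict inequalities, so a
leukocyte at e = 0.8 exactly is not flagged. "Spleen" and "Microcircle"
are kept verbatim as taxonomy names; their semantics here are the
documented spherocyte-like (pallor absent, round, normal size) and
microcyte-like (small, round) rules. The leukocyte "activity" gradient
score is a documented stand-in: the mean boundary gradient against a
caller-supplied population quantile threshold; with no threshold
supplied only the eccentricity condition applies.

Peripheral inclusions are those whose minimum normalized rim depth is
≤ 0.15; Howell-Jolly requires exactly one non-peripheral, non-elongated
inclusion; the Hemoglobin-C rule keys on inclusion eccentricity > 0.8.

## Zero-shot model

The attribute space is the descriptor registry itself, so φ(y) is a
class's prototypical morphometric profile. Fitting minimizes seen-class
softmax cross-entropy with dropout 0.3 on inputs, Adam (lr 0.001, batch
16, ≤ 100 epochs), early stopping (patience 5) on a seeded validation
split, and an L2 penalty of λ = 0.01 **centered on the identity map**.
The centering is load-bearing: a bilinear model with a zero-centered
ridge leaves W unconstrained (hence zero) along attribute directions no
seen class exercises, making classes with orthogonal attributes
unrankable; centering on the identity makes the un-learned behavior
direct descriptor–attribute matching. A `zero` init option exists for
studying optimization from the uniform-softmax start (loss ln K).
The shipped subclass KB contains synthetic prototype vectors (documented
stand-ins, not measured population means).

## Detection and metrics

The baseline detector is classical: luminance, background estimated as
the 90th percentile (robust when cells dominate the frame), Otsu
threshold with a 0.1 luminance floor (so blank frames yield nothing),
morphological opening and hole filling, distance-transform watershed
(peak separation 8 px), components ≥ 30 px, class by a size/color
heuristic. Confidence is a monotone function of area, so ordering is
deterministic.

Matching is greedy in descending confidence, one truth per prediction,
ties toward higher IoU. AP@50 integrates the interpolated
precision–recall envelope over the confidence sweep; at equal
confidence, misses are ordered before hits — a conservative tie-break
that makes metrics invariant to image permutation. Empty-set
conventions: no predictions with truths present → P = R = F1 = 0; both
empty → 1. Confusion matrices match class-agnostically at IoU 0.5
first, then compare classes, with unmatched truths in a background
column and unmatched predictions in a background row.

## Virtual stainer

The desk-scale trainer uses per-pixel (1×1-convolution) networks: a
1→16→3 ReLU generator and a 3→8→pool→logistic discriminator, alternating
one discriminator ascent and one generator descent step per minibatch
under the λ = 10 objective, with discriminator probabilities clipped at
1e−12 before logs. Protocol defaults (lr 2e−4, batch 32, 100 epochs)
mirror the full-scale setting; the desk-scale synthetic colormap task in
tests and the CLI uses lr 0.05 and ≤ 30 epochs, where the ideal
generator is exactly representable and held-out transform loss drops
well past half its initial value. Capacity is deliberately per-pixel:
the harness demonstrates adversarial mechanics and descent, not
photorealistic staining.

## Validation protocol

Stratified k-fold: per class, seeded shuffle dealt round-robin with a
rotating per-class fold offset — deterministic, proportion-preserving
(per-fold class counts within 1), fold sizes within 1. At k = 5 and
n = 8,380 this yields 6,704 train / 1,676 validation per fold. Held-out
sizes round half-up (n = 108 → 22, n = 260 → 52). Paired t-tests are
two-sided with Bonferroni adjustment min(1, p·m); zero-variance
difference series are flagged degenerate instead of reporting a
statistic. Cohen's d uses the paired d_z form, mean(diff)/sd(diff) with
sample sd.

## Deep-feature contract

`ResidualBackbone` is a bottleneck residual CNN with seeded
He-initialized weights and global average pooling into 2048 channels.
The default depth is one block per stage with 64×64 inputs, a
single-CPU-friendly configuration that preserves the embedding contract
(length 2048, deterministic per seed, content-sensitive); the classical
50-layer layout is available as `blocks_per_stage=(3, 4, 6, 3)`. The
weights are never trained in-package: the embedding is a structured
random projection, and any externally fine-tuned backbone can be used
behind `deep_features` provided it honors the 2048-d contract.

## Problem sizes and scope

Defaults throughout are sized for a single CPU: 384² canvases with ~5
cells per image, ~1,000 cells for the rule-engine recall property,
n ≈ 100–400 rows for classifier harness checks, 32² patches for the
stainer. The mono/poly classifier's default mode is a logistic model
over lobe-count-bearing descriptor tables (the discriminative signal is
explicit in the features); no convolutional patch classifier is trained
in-package. Known limitations: rule thresholds are calibrated to the
generator's idealized geometry and will need re-tuning on real stains;
the baseline detector assumes darker-than-plasma cells and moderate
crowding; the subclass KB is synthetic.
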