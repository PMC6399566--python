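# Methods

## The measurement model

The system estimates scoliotic curvature from a single AP radiograph by
reducing each of the 17 thoracolumbar vertebrae (T1–L5) to the tilt of
its endplates and taking the maximum pairwise angle

φ = max_{(a,b): b−a≥2} arctan |(m_a − m_b) / (1 + m_a m_b)|,

where m_a is the upper-border slope of the upper vertebra of the pair
and m_b the lower-border slope of the lower one. Slopes are dimensionless
rise/run in a y-up image frame. The pair constraint b − a ≥ 2 excludes
adjacent vertebrae (a Cobb curve spans at least one full vertebra
interval); the maximising pair is reported as the end vertebrae. The
sign convention is clinical: φ < 0 when the curve bends rightward,
decided by whether the maximising upper slope lies below the lower
slope. Severity bands on |φ|: [0,10) spinal curve, [10,20) mild,
[20,40] moderate, >40 severe (lower bound inclusive; the 40° boundary
belongs to moderate).

Endplate slopes come from the **minimum-area bounding rectangle** (MBR)
of each segmented vertebra. The rectangle is found by the classical
edge-aligned rotating search over the convex hull of the mask's
boundary pixels (the minimum-area rectangle provably shares a side
direction with a hull edge); the two edges whose outward normal is most
vertical are labelled top/bottom, and their common slope provides both
endplate slopes. Masks measured on rescaled 256×128 chips are first
mapped back to the isotropic ROI frame: the chip rescale is anisotropic
and shears tilted shapes, and an MBR computed in sheared coordinates
does not align with the endplates (slope rescaling after the fact is
*not* equivalent — this is why segmented vertebrae are reconstructed
into the spine frame before any angle is read off).

## Pipeline stages and their parameters

**ROI isolation.** The film is block-averaged to quarter size (smooth
projection profiles; cheaper windows). Column band: the contiguous run
around the vertical-projection maximum with values ≥ mean + c·σ,
c = 1 by default; the selected band is padded by 15 quarter-scale
pixels per side because the band hugs the spine and the downstream
boundary search needs room outside the cortical edge. Row band: the
global minimum among local minima of the upper half of the horizontal
projection (the dark gap between skull and T1) and the largest
single-step discontinuity in the lower half (the pelvis). A principal
-axis pre-rotation is available but off by default; upright acquisition
is assumed.

**Vertebra detection.** Window defaults H = 51, W = 13, p = 12 (step
down), q = 10 (lateral search), r = 40 (boundary reach), n = 6
reference points per central line segment, sibling windows 11×5. These
are tuned for vertebrae appearing ≈50 px tall on the quarter image,
which matches both clinical films of a few thousand pixels and the
phantom defaults. Central line segments are fitted with a degree-2
polynomial (stable with 6 points); boundary curves with degree 3. Both
fits take one robust rejection pass (drop residuals > max(3–4 px,
3×median), refit): a reference point that lands on a noise ridge, or a
boundary point from a weak disc-row edge, would otherwise swing the
local polynomial and every normal computed from it. The recorded
boundary split is shifted half a pixel outward to undo the window
-rounding bias.

**Voting.** Thresholds γ_t = 16t, t = 1…15, applied to the outer two of
three equal-width column bands between the boundary curves (the middle
third, which contains the bright spinous column in the low thresholds,
is excluded). Retained pixels project to the nearest CSC sample
(KD-tree nearest neighbour ≈ perpendicular foot at this sampling
density, and keeps the counts integral). A "drastic rise" seeds a cut
when P climbs by θ = 8 votes (a majority of the 15) within a 6-bin
trailing window; from each seed, the first global maximum of a 15-bin
sub-histogram places the cut. Consecutive cuts, complemented by the ROI
top/bottom, bound the vertebra boxes; an interval whose votes never
drop below θ contains no bone and is discarded (bare end-disc regions).
Chips are cropped with a 15% contextual margin — tilted vertebral
corners extend past the horizontal cuts, and the margin keeps them
inside the chip so the rectangle stage sees the whole body.

**Segmentation.** Three encoder-decoder variants share one scaffold
(concatenation skips, 2×2 max-pool encoder, 2×2 stride-2 transposed
-convolution decoder followed by a 3×3 channel-halving convolution and
the skip concat, 1×1 head, logistic squashing to [0,1], masks by
thresholding at 0.5):

* *unet*: two (3×3 conv → ReLU → batch-norm) units per level;
* *residual*: one pre-activation residual block per level,
  x + F(x) with F = (BN → ReLU → 3×3 conv) × 2 and a 1×1 projection on
  the skip when the channel count changes (preserves the identity
  semantics across levels — the identity form is asserted numerically
  in the tests by zeroing the branch);
* *dense*: an l-layer dense block of growth rate k per level — each
  layer consumes the concatenation of all previous outputs, the block
  emits l·k channels, and a 1×1 transition restores the level's nominal
  width.

Training: Adam, batch 10, learning rate 0.01, up to 100 epochs, L2
(mean-squared-error) loss between the probability map and the binary
mask; per-fold augmentation to a target count by rotation ±5°,
translation ±5 px and intensity gain 0.9–1.1; 10% of the augmented set
held out for validation; 5-fold cross-validation assigns folds at the
image level so chips from one radiograph never straddle train and test.
The layer stack is pure numpy (im2col convolutions over BLAS, explicit
backprop, verified against finite differences in float64); it exists
because the package targets plain CPU environments, and the networks
at issue are small enough for this to be practical.

A training-free **classical segmenter** (Otsu threshold, components
restricted to those reaching the chip centre, largest kept, holes
filled) lets the full pipeline run without any fitted weights; on
phantom chips it is nearly as accurate as the networks because the
phantom's vertebra/background contrast is clean.

## The phantom

The generator emulates exactly the image structure the pipeline
exploits, with analytic ground truth (per-vertebra masks, corner
quadrilaterals, endplate slopes, the Cobb angle implied by those slopes
via the same pair search the measurement uses):

* frame 4800×2800 px (the scale of clinical full-spine films, so the
  quarter-scale window defaults are exercised as intended);
* 17 vertebrae, 180 px tall × 280 px wide, 60 px intervertebral gaps,
  stacked along a quadratic bow whose amplitude is solved from the
  requested Cobb angle; vertebra tilts follow the local tangent, as
  they do anatomically;
* bone intensity 230 with a thoracic→lumbar linear ramp ×(0.95→1.10)
  (lumbar vertebrae image brighter), modulated transversely by a
  projected-dome profile 0.55 + 0.45·√(1−(2x/w)²) — the X-ray path
  through the vertebral body and spinous process peaks at the midline,
  and this central brightness is precisely what anchors the
  maximum-intensity window tracking; the 0.55 floor keeps the lateral
  cortical edge sharp;
* discs at soft-tissue + 0.10 × (bone − soft-tissue): clearly darker
  than bone, which is what makes disc bins collect ≥8 more votes than
  vertebra bins under the γ_t ladder;
* a soft-tissue torso band (level 60) against dark air margins (30) —
  the column-projection ROI rule works on real films because the torso
  is a wide bright band, so the phantom must have one;
* a skull clipped at the frame top (neck gap above T1 for the row-band
  minimum) and a sharp-edged pelvis band below L5 (the row-band
  discontinuity);
* additive Gaussian noise (σ = 4), clipped to [0, 255], applied after
  all structures; masks are rendered noise-free.

What the phantom does **not** model: pedicles, rib shadows, texture,
exposure inhomogeneity, implants, anatomical shape variation, or
end-vertebra selection ambiguity. Passing tests therefore demonstrate
the geometric and algorithmic correctness of the pipeline under the
image structure it was designed for, not clinical-grade robustness on
real films — the packaged observer-agreement table is the only clinical
evidence shipped, and it is recomputed, not re-measured.

## Desk-scale experiment sizes

The shipped experiments are sized for a single CPU:

* **Cobb recovery**: 50 phantoms with |φ| uniform in [5°, 45°], both
  bow directions. Feeding ground-truth masks into the MBR + pair
  search recovers the angle within ±2° in 50/50; the full classical
  pipeline within ±5° in 50/50 (signed error ≈ 0.0 ± 1.7°).
* **Segmentation cross-validation**: 10 phantom images → 170 chips at
  64×32, depth-3 networks with 4 base channels (growth 4, 3 dense
  layers per block), 5 folds, augmentation to 160 per fold, 8 epochs,
  learning rate 0.003. The reference rate of 0.01 belongs to the
  full-width 256×128 configuration; on these narrow desk-scale models
  it oscillates (the residual variant can stall at chance), so the
  desk experiments use 0.003 — a size-coupled optimisation choice, not
  a change to the training contract, whose default remains 0.01. All
  three variants reach mean Dice ≥ 0.97 with a spread < 0.02.
* **Oracle checks**: the pair search against exhaustive enumeration on
  100 random slope configurations (exact agreement required); the
  rectangle search against a 0.1°-step rotation sweep on 50 random
  blobs (area within 0.5%).

## Numerical conventions

* Intensities are floats in [0, 255] regardless of file bit depth;
  RGB inputs collapse to the channel mean.
* Downscaling crops to a multiple of 4 and block-averages.
* Empty-denominator conventions in the metrics: similarity = 1 and
  error = 0 when both masks are empty (trivial perfect agreement);
  Dice = 2·J/(1+J) is asserted as an identity in the tests.
* Spearman's ρ uses the rank-difference formula on average ranks; with
  ties it is an approximation of Pearson-on-ranks (they agree exactly
  tie-free, which the tests verify); p-values come from the exact form.
* Descriptive SD uses the population (n) denominator — required to
  match the reference summary of the packaged table.
* ICC defaults to the two-way random-effects, absolute-agreement,
  single-measure form ICC(2,1) (via pingouin), configurable to ICC(1,1)
  or ICC(3,1). The verbal bands are poor < 0.40 ≤ fair < 0.60 ≤ good
  < 0.75 ≤ excellent.
* "No scoliosis" entries in the measurement table are zero-filled (with
  flags), not case-deleted; session t = 1 feeds the agreement battery
  by default because the reference summary's ranges match that session.
* Ties in the window searches break to the leftmost window; ties in the
  pair search to the smallest (a, b); the "first global maximum" of a
  vote sub-histogram is the smallest index attaining the maximum.
* Degenerate inputs degrade with warnings rather than exceptions where
  a downstream stage can still proceed (flat projection profiles, masks
  touching the chip border, perpendicular endplate pairs); hard
  failures (fewer than 3 vertebrae) raise with stage diagnostics.

## Known limitations

* The boundary cubic under-tracks very strong curves (≥40°) near the
  convex apex; the voting and rectangle stages absorb most of it, but
  per-boundary error grows with curvature.
* Horizontal cuts cannot fully separate steeply tilted neighbours
  whose endplate row-spread exceeds the disc gap; the chip margin
  mitigates this, and the residual effect is a slight magnitude
  underestimate at large angles.
* The classical segmenter assumes bimodal chips; on low-contrast real
  films the network path is the intended route.
* Training the numpy networks at the full 256×128 / 64-channel scale is
  possible but slow on one CPU; the package treats channel widths and
  chip size as configuration.
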