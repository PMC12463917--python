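# Methods

## The detection model

The detector assumes a single quasi-spherical fruit on a dark, weakly
saturated background.  In HSV, the peel is strongly saturated while the
background is not, so one global Otsu threshold on the S channel separates
fruit from background; the removed background is written as the reserved
gray level 0 and fruit saturation is clamped to a minimum of 1 so that 0
stays unambiguous.  Defects (scars, spots, rot patches) appear as *locally*
low-saturation regions, but the global radial shading of a round fruit means
no single threshold separates them everywhere — hence local windows.

Each `n × n` window of the masked S image is classified by its count of
reserved zeros: all-zero windows are background and skipped; windows with
more than 1/20 zeros straddle the rim ("edge"); the rest are interior
("foreground").  Edge and foreground windows build a zero-excluded
histogram.  Without that exclusion, Otsu's threshold in a rim window lands
at 0 — it separates fruit from background instead of defect from peel,
which is the failure mode the window classification exists to fix.

The inter-class average grayscale difference `Δd = |m₁ − m₂|` between the
two Otsu classes acts as a defect-evidence gate.  A clean window (shading
plus noise only) produces a small `Δd`; a genuine defect produces a `Δd`
near the defect's saturation contrast.  Only gated windows are binarized
(`sound = S > T`); everything else adopts the fruit mask, so the number of
true local thresholdings — logged per run — stays far below the window
count.  A degenerate split (one empty class, e.g. a perfectly uniform
window) carries no evidence and never passes the gate; its `Δd` is recorded
as undefined.

Two passes are run: the primary grid at the origin and a secondary grid
offset by `(n/2, n/2)`, which re-cuts every interior defect at different
window boundaries.  Each pass yields a defect map (fruit minus its sound
surface, restricted to the pixels that pass actually covered — the offset
pass leaves an `n/2` frame uncovered).  The fused map is the weighted
combination `α·I₁ + β·I₂` binarized at > 0 with `α > β ≥ 0`; for binary
inputs and `β > 0` this is exactly the union, so a defect found by either
pass survives and the uncovered pass-2 frame falls back to pass 1.  The
implementation states this equivalence outright instead of attributing
meaning to particular weight values.  The same union-of-evidence rule is
applied *within* a pass when windows overlap (the optional `step = n/2`
mode).

Refinement is morphological: closing (default 7×7 disk) fills voids inside
detected patches, opening (default 3×3) removes specks and burrs, and
components under `min_area` (default 30 px) are dropped.  Named policies
(`small` 5/3, `medium` 9/5, `large` 11/7) encode the size trade-off —
small openings preserve small defects but keep more noise; large ones clean
harder but erode detail.  The policy is chosen by configuration, never
switched automatically.

Stems: among the final components, one that is compact
(circularity `4πA/P² > 0.8`) **and** yellow-green (circular mean hue within
23–35 on the half-degree wheel) is declared the stem and removed from the
defect set.  Both criteria are required: defects with peel-like hue stay
defects however round they are, and elongated yellow-green regions stay
defects too.

## Parameters that matter

| parameter | default | unit / range | why |
|---|---|---|---|
| `window_n` | 100 | px | trade-off between locality and work; 400×400 inputs give a 16 + 9 = 25-window budget |
| `delta_gate` | 30 | gray levels | below typical defect contrast (~60), above shading + noise within one window |
| `step` | `n` | px | `n/2` enables 50 %-overlap scanning |
| `alpha`, `beta` | 0.6 / 0.4 | – | fusion weights, `α > β ≥ 0`; any positive pair is the union |
| `se_policy` | `default` (7/3/30) | px | refinement structuring elements and minimum area |
| `circ_min` | 0.8 | – | stems are near-elliptical; a 2:1 ellipse sits near 0.82–0.84 |
| `hue_lo..hue_hi` | 23–35 | half-degrees | stem hue band (46–70 true degrees); both bounds configurable, including a wrap-around band, to cover the alternative 360° reading |
| `min_pixels` | 20 | px | edge slivers with fewer nonzero pixels carry no usable histogram |
| `match_iou` | 0.3 | – | region-level match acceptance for evaluation |

Hue convention: hue is stored on the 8-bit machine-vision wheel `[0, 180)`
(one unit = two degrees) throughout; the 23–35 stem band is interpreted on
this scale.

## The synthetic scene generator

The generator emulates the statistical structure the detector relies on,
not photorealism:

* **Fruit disk** with quadratic radial falloff
  `S(ρ) = S_c · (1 − (1 − f)·(ρ/R)²)`.  Defaults: `S_c = 210`,
  saturation falloff `f = 0.82`, value falloff 0.75.  The split is
  deliberate: the strong limb darkening of a sphere lives in the value
  channel, which the detector never thresholds, while the saturation
  falloff is milder.  The saturation default is pinned by the method's own
  premise, worked out analytically before any end-to-end test was written:
  a rim window spans ~96 % of the total falloff, so sound windows need
  `S_c(1−f)·0.55 < 30` (gate headroom, `f ≳ 0.65`) and a 60-level defect
  separates from shading only if `S_c(1−f)` stays clearly below 60
  (`f ≳ 0.81`).
* **Defects**: `point_like` (one compact ellipse; scars/spots) and
  `blocky` (a union of 3–6 jittered sub-ellipses; diffuse rot/sunburn),
  both subtracting saturation (default 60) and value (default 30) inside
  the patch.  Suite point defects use semi-axes 13–22 px — about 0.25–0.4 cm
  at the ~53 px/cm scale of a 400×400 fruit crop, typical of spot lesions —
  placed within 0.8 R of the center (near-rim patches are foreshortened on
  a sphere and rarely visible face-on).  Blocky patches use 28–45 px
  envelopes with contrast 50.
* **Stem**: an ellipse (axis ratio ≤ 2.2, so its rasterized circularity
  stays above 0.8) with hue 26–33, saturation 70, value 120, i.e. a dark
  yellow-green button that window segmentation will flag and the stem
  filter must rescue.
* **Noise**: additive Gaussian, σ = 3 8-bit levels per RGB channel,
  applied after shading; masks are exact rasterizations and carry no noise.
* **Suites** mix 20 % sound / 40 % point / 20 % blocky / 20 % stem scenes
  (largest-remainder rounding gives exact per-label counts); stem scenes
  also carry one point defect so stem rejection and defect retention are
  exercised together.

What the generator does **not** model — and what passing tests therefore do
not show: specular highlights and glare, texture of real peel, soft defect
boundaries with partial contrast, shadows, multiple fruit, camera optics,
and lighting-condition variation.  Synthetic results bound the algorithm's
logic, not its field accuracy.

## Numerical choices and degenerate inputs

* Otsu threshold: smallest maximizer of the between-class variance on
  ties; computed in the cancellation-free cumulative form
  `(μ_T ω₁ − μ)² / (ω₁ω₂)`.  A single-occupied-bin histogram returns that
  bin with a degenerate flag downstream.
* Circularity uses the 4-direction Cauchy–Crofton perimeter estimate.  A
  naive boundary-step count overstates the perimeter of smooth rasterized
  shapes by ~5–8 %, which would push a legitimate 2:1 elliptical stem
  (continuous circularity ≈ 0.84) below the 0.8 threshold; the Crofton
  estimate keeps a disk at ≈ 0.99 and that ellipse at ≈ 0.82.  Components
  under 5 px have no meaningful shape and are never stems.
* Mean hue is a circular mean on the `[0, 180)` wheel (two antipodal hues
  average to their wrap-around midpoint, not 90).
* Background segmentation declares "no fruit" when the upper global-Otsu
  class has mean saturation below 100: splitting a fruitless image only
  divides background noise, whose upper class sits far below any real peel.
  A one-gray-level image raises a degenerate-histogram error instead.
* Mask rounding at the rim can retain a few dark background pixels inside
  the fruit mask.  If more than `min_pixels` of them land in one window
  they form a genuine second class and trigger a local thresholding even on
  a sound fruit; the flagged pixels are sub-`min_area` and removed at
  refinement, so the effect is a rare +1 in the thresholding count, not a
  false detection.
* Evaluation: pixel-level TN is restricted to the fruit mask so the image
  background cannot inflate specificity; region-level TN is undefined and
  reported as 0 (FPR unavailable).  Metrics with zero denominators are
  reported as undefined (`None`), never as 0.

## Design choices that were genuinely open

* **Fusion polarity.** Binarized per-window results could be fused as a
  union of *sound* surface or of *defect* evidence.  Union-of-sound lets
  either pass veto the other (a defect cut into small fragments by one
  pass's grid would erase the other pass's whole detection), and would make
  the second pass strictly harmful; union-of-defect makes the two passes
  complementary, which is the point of offsetting them.  This package fuses
  defect evidence.
* **Threshold polarity.** Defects are taken as the low-saturation Otsu
  class (`sound = S > T`); an `invert` flag exposes the opposite
  convention.
* **Hue wheel.** The 23–35 stem band is read on the half-degree `[0, 180)`
  wheel; both bounds are configuration, so the 360°-wheel reading
  (46–70 → 23–35 true degrees) can be expressed without code changes.
* **Region matching.** Predicted and true defect regions are matched
  greedily by descending IoU with a 0.3 acceptance threshold, one-to-one.
  On suites with few, well-separated components this equals the exhaustive
  optimal assignment (property-tested).

## Problem sizes used by the test and acceptance runs

Tests and the acceptance script run entirely on generated scenes:
100-scene suites for end-to-end recovery, 50-scene suites for the ablation
directions (gate 20/30/40, circularity 0.7/0.8/0.9, windows 100/50/20),
200 random histograms for the brute-force Otsu comparison, and 40
stem-plus-defect scenes for the stem end-to-end property.  A full
acceptance run takes roughly half a minute on one CPU; the complete test
suite a few minutes.

## Known limitations

* Defects whose contrast is comparable to the within-window shading spread
  (very shallow rot near the rim) fall below the `Δd` gate and are missed —
  the same trade-off the gate is designed to make.
* Diffuse blocky defects can fragment into several predicted components;
  region-level counting then reports extra false-positive fragments even
  though the pixels are correct.
* A stem touching or overlapping a defect merges into one component whose
  shape/hue is mixed; the filter then keeps it as a defect (conservative
  direction).
* Single fruit per image; no calyx-vs-stem distinction; no multi-scale
  window selection — the window size is a fixed configuration choice.
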