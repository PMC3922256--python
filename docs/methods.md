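# Methods

This note documents the model, the numerical choices, and the synthetic
data that the test suite measures the implementation against.

## Problem and decomposition

A clinical tongue photograph shows facial skin, lips, a dark
mouth-opening region, and the tongue body protruding below the two
mouth corners (the *angular points*). Segmentation must recover the
closed tongue outline despite weak or ambiguous color boundaries
(pale tongues against skin, red tongues against lips).

The method exploits the geometry of the scene: the row of the angular
points, `sline`, splits the region into an upper part (tongue root,
mouth opening, lips, possibly a nose) and a lower part (tongue body
against skin). Each part gets the contour model that suits it — a
geodesic level-set flow below, a gradient-vector-flow (GVF) snake
above — and the two arcs are joined at the angular points.

## Stage by stage

### Saliency window

The tongue complex is the most color-salient structure, so the region
of interest is the rectangle that best composes the saliency mass.
Saliency = per-pixel CIELAB distance to the global mean color,
Gaussian-smoothed (σ = 3 px) and min-max normalized; a constant image
yields an all-zero map. The window objective is

    score(W) = S_in(W) − p·S_margin(W) − q·area(W)·mean(S)

with `p = 1` (saliency left in a band just outside the window, band
width 10 % of the smaller window side, minimum 2 px) and `q = 1.5`
(area regularizer in units of mean saliency). The margin term makes
the window swallow whole salient structures; the area term keeps it
from swallowing the frame and separates disjoint structures. Search is
exhaustive over positions via integral images and coarse-to-fine over
sizes with greedy edge refinement; on small maps (≤ 64×64) it is fully
exhaustive, which the tests compare against a brute-force scorer. Two
windows are detected (the second after suppressing the first;
candidates scoring < 5 % of the best are discarded as suppression
leftovers) and the smaller is adopted, then padded by 10 px for the
crop so the mouth corners stay clear of the crop border.

### Feature points

*Angular points.* Harris corners (σ = 2.5) inside the central row band
(25–80 % of the crop height, which excludes nose and border
artifacts); in each horizontal half the lowest sufficiently strong
response (≥ 20 % of the half's maximum) is the rough corner — the
mouth corner is the bottom-most corner-like junction of the mouth
complex. The rough estimate is then refined by color: pixels within
RGB distance 0.12 of a tongue seed color (sampled well inside the
body) form the tongue-colored set; its lateral extreme inside a ±15 px
window marks the true junction, after discarding speckle components
(< 12 px). When the tongue color is close to the lip color, the set
merges with the lip, the extreme column degenerates into an extended
vertical edge (row span > 6 px) and the refinement is declined — the
rough Harris point is kept. This graceful degradation is exactly the
clinically hard case (red tongue class) and is what reproduces its
lower accuracy.

*Tip and root.* On the vertical midline between the corners (5-column
average, Gaussian-smoothed), the tip is the **lowest** row whose
vertical-gradient magnitude reaches 50 % of the below-`sline` maximum:
deliberately biased at-or-below the true tip, because the lower flow
can only shrink. The root is placed 3 px below the lowest strong edge
above the angular row (the tongue / mouth-opening transition),
strictly inside the body, because the upper arc can only swell.

### Initialization

The initial contour is the quadratic arc through (left corner, tip,
right corner), bowed outward between its anchors (the chord-depth
profile is raised to the power 0.65, which leaves the three anchors
fixed and pushes everything between them outward) — so it encloses any
true boundary through roughly the same three points — closed by
straight segments corner → root → corner that lie inside the body.
`sline` is the rounded mean of the two corner rows. The level-set
matrix is −ρ strictly inside, 0 on, +ρ outside the contour (ρ = 2);
the negative interior fixes the shrinking direction. The upper crop is
binarized by a fraction-guarded recursive Otsu: the dark class is
re-split while it covers more than 35 % of the upper crop, because the
mouth-opening strip (height at most about twice the lip thickness —
the same prior the nose-removal rule uses) can never occupy a third of
it. Rows far above the lip are cut at `top(dark strip) − 2·height`,
which removes any nose block.

### Lower flow: distance-regularized geodesic level set

    ∂Φ/∂t = μ[ΔΦ − div(∇Φ/|∇Φ|)] + λ δ_ε(Φ) div(g∇Φ/|∇Φ|) + ν g δ_ε(Φ)

* weights μ = 1, λ = 3, ν = 0.5 — the published operating point of
  this flow; ν > 0 shrinks a negative-inside initialization;
* **intensity scale**: the edge indicator `g = 1/(1+|∇(G_σ*I)|²)` is
  computed on the native 8-bit scale (I·255). The weight regime above
  presumes gradients of that magnitude; with unit-interval intensities
  `g` stays ≈ 1 everywhere and nothing ever stops the curve;
* σ = 1 px. A narrower kernel localizes the `g` valley: the converged
  contour sits ~0.5 px from a sharp edge, versus ~1.3 px at σ = 1.5
  (the contour parks at the outer wall of the valley floor, which
  widens with σ);
* regularized Dirac δ_ε(Φ) = (1/2ε)(1+cos(πΦ/ε)) on |Φ| ≤ ε, ε = 1.5;
* explicit Euler with τ = 0.2 under the guard τ·μ < 0.25 (the
  Laplacian CFL bound for the distance-regularization term);
* update restricted to rows ≥ `sline`; rows above keep their initial
  values bit-exactly (the stencil reads two frozen rows above the
  split, so restricted and unrestricted updates agree on the evolved
  rows);
* convergence: the {Φ < 0} pixel set unchanged for 20 consecutive
  iterations, at most 1200; front speed is ~0.07 px/iteration, so the
  cap accommodates ~50 px of travel plus settling. No
  re-initialization is performed at any point.

The first few steps of the flow reshape the piecewise-constant
initialization toward a signed-distance profile, during which the
enclosed area can fluctuate by a few pixels; monotone shrinkage on
edge-free images holds after that brief relaxation, and the tests
allow a 5-iteration burn-in accordingly.

### Upper flow: binary-map GVF snake with geometric propulsion

The GVF field relaxes V toward ∇B at the strip edges and diffuses it
elsewhere: diffusion is explicit within its 4-neighbor stability bound
(dt = min(1, 0.25/w), w = 0.2 within the conventional GVF range), the
reaction term is semi-implicit (unconditionally stable, same fixed
point; the residual ‖w∇²V − |∇B|²(V−∇B)‖∞ is driven below 10⁻³ on
test fixtures). The field is identically zero at and below `sline`.

The snake is the open arc between the pinned angular points, solved
semi-implicitly for the internal forces (pentadiagonal system from
αC'' − βC'''', α = β = 1, with linear-extrapolation ghost nodes at the
pinned ends so a straight evenly spaced arc is exactly stationary) and
explicitly for the external force. The published external force
"max(V_B, G_B)" is not defined for vectors; the prose semantics —
vector-flow attraction near the boundary, outward propulsion far from
it, and the binary map preventing over-learning — are realized as a
three-regime switch per contour point p:

1. **region stop**: if B(p) ≥ ½ the point has crossed into the dark
   mouth region (non-tongue territory in the upper part) and retreats
   along −n̂;
2. **attraction**: if ‖V_B(p)‖ ≥ θ_v (θ_v = 0.05) the force is V_B(p);
3. **propulsion**: otherwise G_B(p) = g_B(p)·n̂, the edge-stopped
   outward push (g_B is the edge indicator of the smoothed binary map,
   σ = 1, same 8-bit scale).

Without the region stop the relaxed field points *into* the strip from
both sides and the only equilibrium is the strip's medial axis; the
region stop pins the equilibrium to the strip's tongue-side edge,
which is the visible tongue boundary. Outward normals are oriented
away from an interior reference point inside the body. The arc is
resampled to ~1 px spacing every iteration; the step size starts at
0.5 px and is halved (at most 4 times) whenever a 30-iteration window
shows the arc oscillating in place rather than travelling — the
regime switch produces a limit-cycle flutter at the boundary whose
amplitude scales with the step. Convergence: maximum displacement
< 0.05 px for 10 consecutive iterations, at most 400.

### Assembly

The zero isoline of the final Φ (marching squares, sub-pixel) is split
at `sline`; its lower run is joined with the converged upper arc into
one closed contour and rasterized (pixel centers inside or on the
polygon; self-intersections near the junctions are repaired before the
point-in-polygon test). The pipeline is fully deterministic: identical
image, configuration and seed give bit-identical masks.

## Metrics

Boundary: symmetric Hausdorff and symmetric mean nearest-point
distance, point-to-point on ~1 px resampled contours, normalized by
the image diagonal and reported in percent (the reference-contour
length is available as an alternative normalizer). Area: FP/FN/TP
volume fractions of the automatic mask relative to the reference area,
so TP + FN = 100 exactly.

## Synthetic scenes

Each scene renders, on a 256×256 canvas: skin background; a tongue
body bounded by two quadratic arcs meeting at the angular points (apex
= root above, tip below); a dark mouth-opening strip of constant
height (default 6 px) that thins linearly toward the mouth corners
over 10 columns — the lips close onto the tongue there, so the corner
neighborhood is a pure tongue/lip junction; a lip band (10 px) above
the strip; an optional shaded nose block; and seeded additive Gaussian
noise (σ = 0.02, clipped). Geometry, palette and noise all derive from
the scene seed, and feature points / masks are exact by construction.

Class palettes mirror the four clinical tongue-color classes. The red
tongue is nearly lip-colored (RGB distance 0.03 — the documented hard
case), light-white is a pale pink clearly distinct from both lip and
skin, purple and carmoisine sit between. Tongue-lip contrast matters
at the corners (where lips touch the tongue) and drives the corner
refinement's accept/decline behavior, which reproduces the clinical
ordering: red scores the worst corner localization, hence the lowest
mean TP.

What the scenes deliberately omit: teeth, coating texture, specular
highlights, lighting gradients, lens distortion. Passing tests
therefore demonstrate the geometry and contrast logic of the method —
correct flows, stopping behavior, partition bookkeeping, metric
arithmetic — not robustness to photographic nuisance factors; on real
clinical images the detectors (saliency, Harris, thresholds) would be
the components most exposed to those factors.

Suite sizes used by the tests: 20 mixed-class scenes for end-to-end
recovery (a desk-scale stand-in for a clinical collection, chosen so
the whole suite reruns in a couple of minutes), 10 scenes per class
for the class-ordering comparison (paired geometry: the class suites
share seeds, so they differ only in palette).

## Degenerate inputs and guards

* constant image → saliency is all-zero and detection fails loudly;
* empty saliency map → no windows; empty candidate list → detection
  error; equal-area window tie → higher score wins;
* gradient norms are guarded by √(‖∇Φ‖²+10⁻¹⁰); non-finite values in
  any flow raise a divergence error naming the term;
* zero-area contour slivers rasterize as their boundary pixels only;
* an empty dark region makes nose removal a logged no-op;
* τ = 0 is accepted by the step function as the identity (testing
  hook); the pipeline configuration enforces τ·μ < 0.25.

## Known limitations

* The upper arc's equilibrium is the strip's tongue-side edge; if the
  mouth opening is not visible at all (strip absent), the upper flow
  has only the propulsion and region geometry to work with.
* The corner refinement assumes the tongue is the dominant
  tongue-colored component near the corners; heavy coating that
  recolors the margin would defeat the seed.
* Boundary placement is accurate to roughly half a pixel; the FP
  fraction on synthetic scenes (~1–2 %) is dominated by a sub-pixel
  ribbon along the long lower boundary and by the thin strip remnant
  near the corners, not by gross errors.
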