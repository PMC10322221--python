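# Methods

This note records the measurement models the package implements, the
numerical choices made where the procedure was genuinely open, what the
phantom generator does and does not emulate, and the known limitations.

## Coordinate and unit conventions

Pixels are addressed as x = column, y = row, origin top-left, 0-based pixel
centers. Masks are rasterized by pixel-center inclusion. Physical
calibration uses the papillary diameter (PD): the optic disc is assumed to
span 1.5 mm, so `mm_per_px = 1.5 / PD_px`. Diameters are reported in µm
(`d_px × mm_per_px × 1000`); curvature in px⁻¹ by default, with an optional
conversion to mm⁻¹ (divide by mm_per_px); reported tortuosity is
additionally scaled ×1000, the convention used in population tables.

## Image conditioning

Order: ROI → median denoise → mean calibration + resampling → CLAHE.

- **ROI (camera aperture).** Threshold the red channel at 1/3 of its mean
  (comparison `≥`, with a strict-positive guard so an all-black frame is an
  error rather than an all-true mask), keep the largest 8-connected
  component, smooth the boundary with a disk opening (radius 5 px at a
  1024-px working size, scaled proportionally), and re-take the largest
  component in case the opening split a neck. This makes the operation
  idempotent: re-extracting the ROI of an ROI-masked image returns the
  same mask.
- **Grayscale.** `Gray = 0.299 R + 0.587 G + 0.144 B` by default. The blue
  weight 0.144 makes the coefficients sum to 1.03 rather than 1; the
  conventional 0.114 triple is available via `gray_coeffs`. Output is not
  clipped.
- **Mean calibration.** Additive per-channel shift to the reference means
  (clipped to [0, 255]); a multiplicative gain is available via config. In
  batch use the reference means are the means of the processed set; for a
  single image they must be supplied (or calibration is skipped).
- **CLAHE.** `skimage.exposure.equalize_adapthist` with an 8×8 tile grid.
  The package's `clahe_clip` follows the common contrast-limit convention
  (default 2.0) and maps to the normalized clip fraction as `clip / 100`.
- Defaults: working size 1024², median kernel 3, CLAHE clip 2.0 / tiles 8.

## Classical vessel candidates

When no external vessel mask is supplied, the dark region of the enhanced
grayscale image is taken by Otsu's threshold computed over ROI pixels. The
threshold exactly maximizes the between-class variance w₀w₁(µ₀−µ₁)² over
all distinct-intensity cut points (no histogram binning — the enhanced
image is float-valued); the dark class is `gray < t`. Components are kept
if elongation (major/minor second-moment axis ratio) ≥ 3, width
(2 × max interior distance-to-background) ≤ 40 px, and area ≥ 50 px, at the
1024-px scale. This classical chain is a deliberately simple stand-in for
a learned segmenter; externally produced masks are ingested unchanged and
preferred when available.

## Segmentation scoring

Acc = (TP+TN)/total, Sens = TP/(TP+FN), Spec = TN/(TN+FP),
IoU = TP/(TP+FP+FN), DICE = 2TP/(FP+2TP+FN), counted over ROI pixels
(full-frame counting available via config). Ratios with zero denominator
are reported as missing (NaN), distinguishing "no positives exist" from
"all missed". Batch aggregation offers pooled (sum confusion matrices,
default) and per-image-mean modes; the DICE = 2·IoU/(1+IoU) identity holds
only for pooled.

## Optic disc

Seed → polar boundary → minimum enclosing circle → calibration.

- **Seed.** Centroid of the largest component above the 99th intensity
  percentile of the Gaussian-smoothed (σ = 5) image within the ROI, or a
  user-supplied point. This brightness heuristic exploits the disc being
  the brightest large structure in disc-centered fundus images.
- **Boundary.** The image is unwrapped to polar coordinates about the seed
  (360 angles, radial extent 0.4·min(H, W), 2× radial oversampling). Each
  angular row is filtered with a 1-D derivative of Gaussian (σ = 2 px)
  along the radius. Dark vessels beyond the rim also produce strong
  bright-to-dark drops, so the rim is taken as the *innermost* drop
  reaching 30 % of the strongest drop anywhere, walked to its local
  minimum and refined to sub-pixel by a parabolic fit; the radius profile
  is median-smoothed across angles (circular window 9).
- **Circle.** Welzl's move-to-front minimum enclosing circle over the
  boundary points (deterministic: fixed-seed internal shuffle), verified
  in tests against an exhaustive pair/triple oracle. Center and diameter
  of that circle define the disc; `mm_per_px = 1.5 / diameter` exactly.

On synthetic discs of radius 30–150 px with seeds up to 20 % of the radius
off-center, the recovered diameter is within ~1 %.

## Centerline graph

Topology-preserving thinning (Zhang–Suen, via scikit-image) reduces the
mask to a 1-px, 8-connected skeleton preserving component and loop counts.
Skeleton pixels with one 8-neighbor are endpoints; pixels with ≥ 3
neighbors are branch pixels, and branch pixels within 2 px (Chebyshev) are
merged into one node at their centroid — digital junctions typically
produce 2–3 adjacent branch pixels, and 4-way crossings two nearby
3-valent pixels, which the merge collapses into a single degree-4 node.
Removing node pixels leaves simple paths/loops, each walked in
deterministic scan order into an ordered segment attached to its end
nodes. Terminal segments shorter than 10 px (spurs — below the 25-px
curvature end-exclusion, so pruning never silently removes measurable
geometry) are pruned; the pruned skeleton is re-thinned so leftover
junction pixels dissolve and degree-2 nodes merge away. Artery/vein labels
transfer to segments by majority vote over an ingested A/V mask.

## Measurements

- **Diameter.** Tangent at a centerline point from a total-least-squares
  line over ±7 path pixels; rays cast both ways along the normal, sampling
  the mask bilinearly (inside = interpolated indicator ≥ 0.5) so the
  boundary is sub-pixel even for oblique vessels; the diameter is the
  Euclidean distance between the two exit points. Sampled every 5 path
  pixels, skipping points within the tangent window of a node. Bars of
  width 5–21 px at 0–60° are recovered within ~0.5 px.
- **Curvature/tortuosity.** B and C are 25 path-steps either side of A
  (matching the 25-px end exclusion); C_A = 2 sin A / |BC|; sin A < 10⁻⁶ is
  treated as collinear (zero curvature) for stability at the formula's
  singular point. Tortuosity pools all samples by default
  (per-vessel-mean-then-mean available). Units px⁻¹ (mm⁻¹ optional).
- **Fractal dimension.** Box sizes ε = 4, 8, …, ⌊min(H, W)/4⌋ (powers of
  2), grid anchored at the origin; ordinary least squares on
  (log 1/ε, log N). The schedule spans scales where counts are neither
  saturated nor single-box; a filled disk should therefore roughly fill
  its frame (a radius-300 disk in a 640-px frame measures ≈ 1.90, whereas
  burying it in a much larger frame flattens the slope).
- **Density.** Exact integer pixel-count ratio, mask intersected with ROI.
- **Main vessels and branching angle.** Segments with centroid within 2 PD
  of the disc border are eligible; per retinal half (above/below the disc
  center) the segment with the largest mean diameter seeds the main chain,
  extended through branch nodes by the thickest incident segment (ties
  break to the lower id). At each branch node on a main chain, directions
  are fitted (total least squares, oriented outward) to the 10 centerline
  pixels leaving the node along the downstream main (the arm whose far end
  is farther from the disc) and along each branch. Thinning bends the
  centerline toward the junction bisector within about one vessel radius
  of the node, so the fit window starts after skipping ⌈EDT⌉ pixels (the
  local vessel radius at the node) — with this exclusion designed Y-angles
  of 30–90° are recovered within ~2° for vessels up to 13 px wide.
  One angle is recorded per (main, branch) pair; the mean over branch
  nodes within 2 PD is the reported branching angle.
- **AVR** = mean arteriolar / mean venular diameter over the analyzed
  region (and per zone).
- **Zones.** A measurement belongs to the zone of its centerline point;
  distance is (‖p − center‖ − PD/2)/PD from the disc border, binned into
  half-open intervals [inner, outer) — C1 [0.5, 1.0) … C4 [2.0, 2.5) — so
  a point at exactly 1.0 PD is C2. Global metrics use all measurable
  samples; a config flag excludes the disc interior.

## Phantoms

The generator rasterizes exact masks (pixel-center inclusion, no
anti-aliasing) whose ground truth is an analytic function of the spec:
bar width, arc curvature 1/R, designed Y-angle, Sierpinski dimension
log 8/log 3, disc center/diameter. Composite scenes mirror fundus
contrast — bright disc, dark vessels on a mid-intensity background inside
a circular aperture — so the classical segmentation stages can be
exercised end to end; the two vertical main veins carry 45° artery
branches, and thinner peripheral arcs (0.85× vein width, anatomically the
thinner vessels) populate the annuli. Seeded Gaussian noise is applied to
the rendered image only, never the masks, isolating measurement error
from segmentation error. `generate_cohort` ramps vein width 8→16 px and
vessel count 4→8, so measured mean diameter and density must increase
strictly across the cohort. Even integer widths at integer centers would
rasterize one pixel wide; the vertical mains therefore shift to
half-integer columns when the rounded width is even.

What the phantoms do not emulate: intensity gradients across vessels
(Gaussian profiles), central light reflex, background texture and
illumination falloff, arteriovenous crossings with occlusion ambiguity,
motion blur, and realistic vessel taper. Passing tests therefore validate
the geometry and formulas of the measurements, not robustness to real
photographic artefacts.

## Problem sizes

Test and acceptance runs use 400–768-px phantom frames and 10-image
cohorts at 640 px — large enough that every annulus C1–C4 contains
samples and box-counting spans 6–7 dyadic scales, while keeping the whole
suite in the tens of seconds.

## Known limitations

- The three-point curvature estimator reports up to ~1.6·10⁻³ px⁻¹ of
  staircase curvature on rasterized oblique straight vessels (exactly
  axis-aligned or 45° centerlines are collinear and report 0); at
  vessel-scale radii (R ≤ 400 px) the relative error stays below 5 %.
- Branch angles rely on the junction-radius exclusion above; for vessels
  much wider than ~15 px the 10-px fit window sits close to the distorted
  zone and accuracy degrades.
- Crossings are split at degree-4 nodes; no disambiguation of which vessel
  continues through.
- The classical vessel extractor is contrast-based and will under-segment
  low-contrast capillaries; it exists so the pipeline is self-contained,
  not as a substitute for a trained segmenter.
- Quadrant (superior/inferior/nasal/temporal) subdivision is not
  implemented; zones are full annuli.
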