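# Methods

`bifurcbench` re-creates, at desk scale, an in-vitro comparison of three ways
of treating a left-main coronary bifurcation with a stent: a conventional
drug-eluting stent left jailing the side-branch ostium ("keep it open", KIO),
the same stent opened with kissing-balloon inflation (KBI), and a
bifurcation-dedicated stent with a two-strut ostial connector zone (BD-DES).
The pipeline has four layers — geometry, hemodynamics, OCT-style
measurement, and statistics — driven by a synthetic cohort generator
calibrated to published group medians and interquartile ranges.

## Geometry

The lumen is the 2D longitudinal (sagittal, y-up) cut of a Y-shaped vessel:
a proximal channel of width 5.5 mm along +x splitting at the carina (origin)
into a main branch (MB, upward) and a side branch (SB, downward), each
3.5 mm wide, each at 135° to the proximal axis, hence 90° between the
branches. Channel widths are exact by construction (walls are offset lines
of the segment axes). Segment lengths are not part of the published model
description; the full-length default uses 15 mm per segment so a 24–25 mm
device spans the junction, and the CFD cohort profile shortens them (see
*Problem sizes*).

Two geometric regularizations are deliberate:

* **Carina fillet** (default radius 0.3 mm, 0 allowed). A sharp flow-divider
  tip is a reflex corner where the velocity gradient of the continuous
  problem is singular (locally `|∇u| ~ r^−0.46`), so maximum shear rate and
  threshold areas would diverge under mesh refinement. A cast silicone
  divider is rounded anyway; the fillet makes the two shear endpoints
  mesh-convergent quantities.
* **Ostium chord.** The SB opening in the lower wall is the chord from the
  junction corner to the carina-side fillet tangent; with the default
  dimensions its length is 3.50 mm, within 0.6 % of the SB diameter. An
  explicit `ostium_width` rescales the chord about its midpoint.

**Struts.** In the longitudinal cut a strut is an axis-aligned square of
side equal to the strut thickness (81 µm conventional, 70 µm BD-DES).
Wall struts sit at `ring_spacing` intervals (default 1.0 mm, a typical ring
pitch) along the upper wall chain (proximal upper + MB outer wall) and the
lower chain (proximal lower wall, the ostium gap, MB inner wall); floating
struts are spread evenly across the ostium chord. Apposition follows the
OCT rule exactly: floating ⇔ suspended in the ostium; malapposed (MA) ⇔
wall gap strictly greater than one thickness (gaps drawn uniformly in
(1, 2]×thickness, enough to keep the square inside the lumen); well-apposed
(WA) otherwise. WA struts are seated 10 % of a thickness *into* the wall
("flush-pressed"): a strut tangent to a 45° wall pinches the fluid domain at
a point, which no triangulation of a point set can respect, while a seated
strut produces clean transversal notch corners. BD-DES places exactly two
connector struts in a 2.0–2.4 mm ostial zone; with a zero floating budget
they self-position at the ostium ends apposed to the wall, matching the
published zero floating median for that device.

Layout generation is a pure function of (geometry, strategy, spec, mix,
seed); requested apposition mixes are realized by largest-remainder
rounding.

## Meshing

The fluid domain (lumen minus strut squares) is meshed with graded
triangles: boundary rings of the domain polygon are sampled at ~0.9× the
local target size, the interior is filled with nested hexagonal lattices
following a size field (bulk `h_max`, `near_wall_factor × h_max` within one
`h_max` of walls and struts, and an independent cap `h_strut` on strut
surfaces so coarse bulk meshes still resolve the ~80 µm squares), and the
point cloud is Delaunay-triangulated with triangles outside the fluid
removed by centroid and edge-midpoint membership. A midpoint-insertion loop
then enforces two contracts verbatim: no edge anywhere exceeds `h_max`, and
no edge of an element owning a wall/strut boundary edge exceeds
`near_wall_factor × h_max`. The loop also repairs orphaned boundary slivers
(a crossing triangle filtered out near a notch) by splitting the offending
edge. Meshing is deterministic; the mesh sums to the exact polygon area to
1e-6 relative, which the validator asserts on every mesh. At the reference
sizing (`h_max` 0.1 mm, factor 0.25) the full stented model meshes to
~1.6×10⁵ triangles, the same order as the ~95k quad-dominant elements of the
reference analysis; triangles rather than quads are a deliberate choice —
the sizing/refinement contract, not the element polygon, is what the shear
recovery needs.

A strut hovering less than `h_max/10` off a wall (but not touching) is
rejected before meshing with the offending strut id: such a gap is an
unmeshable sliver at the configured resolution.

## Flow

Blood is Newtonian and incompressible (ρ = 1060 kg/m³, µ = 0.0035 Pa·s).
The inlet condition is the bench perfusion: 200 mL/min through the 5.5 mm
circular lumen, i.e. a mean velocity of 0.14 m/s (`inlet_velocity_from_flow`
is the exact Q/(π(D/2)²) conversion). The inlet Reynolds number is ≈233,
firmly laminar, and a precondition rejects Re ≥ 2000. The inlet profile is
parabolic by default (the proximal segment is treated as fully developed); a
plug option exists for sensitivity runs. Walls and strut surfaces are
no-slip; both outlets carry the natural ("do-nothing") condition, the weak
form of the zero-pressure outlets.

Discretization is Taylor–Hood P2/P1 on triangles — inf-sup stable, no
stabilization parameters, and the quadratic velocity space reproduces plane
Poiseuille exactly, which makes the closed-form oracles sharp. The
nonlinear system is solved by Picard (Oseen) iteration with under-relaxation
0.7, switching to exact Newton once the fixed-point residual falls below
0.3; linear systems are solved with SuperLU plus one step of iterative
refinement (the continuity rows are orders of magnitude smaller than the
momentum rows, and the raw LU residual would otherwise dominate the mass
balance). Because the continuity constraint is linear and enforced exactly
at every direct solve, every iterate — and any relaxed combination of
iterates — is discretely divergence-free; net boundary flux of a converged
field is at machine precision (~1e-14 of the inlet flux; the tests assert
<1e-8). Non-convergence raises, carrying the residual history; a converged
field is never silently degraded.

The convergence measure is the RMS velocity change between iterates scaled
by the inlet velocity; the default tolerance is 1e-6, relaxed to 1e-4 for
cohort sweeps (the endpoints are insensitive at that level; the mass balance
is exact regardless).

**Shear rate.** γ̇ = √(2 D:D), D the symmetric velocity-gradient tensor,
evaluated from the P2 gradient at element centroids (element values rather
than nodal extrapolation, for mesh robustness; for pure shear u = (ky, 0)
every interior element returns exactly k). Areas are reported in mm²,
shear rates in 1/s; mesh coordinates are mm, converted to SI for assembly.

## Hemodynamic endpoints

Two scalars per sample: the area with γ̇ above a threshold (default
1000 1/s, the top of the normal arterial 100–1000 1/s range) and the
maximum γ̇. Elements enter the region of interest by centroid membership.
The reference analysis does not state its integration region, so two ROIs
are always reported side by side: a disc of radius one SB diameter centred
on the ostium (where all three strategies differ), and the whole domain.
Exact reproduction of published area values is therefore out of reach by
construction; the *direction* of the contrast is the reproducible claim, and
it is robust here: across seeded cohorts the jailed-ostium strategy's median
ostial high-shear area exceeds the kissing-balloon strategy's in 10/10
seeds (≈0.14 vs ≈0.03 mm²), with maximum shear rates of the same order as
the published 1375–2293 1/s.

## OCT-style measurements

A pullback is 540 frames at 0.1 mm spacing (10 mm/s at 100 frames/s over
54 mm); analysis uses every 10th frame (1 mm intervals). The measurements
are implemented exactly as defined on frame records: strut classification
(floating/MA/WA as above — the MA boundary is strict, a gap equal to the
thickness stays apposed); the elliptical index as the mean over analysed
proximal frames of Dmax/Dmin (the "global extrema" reading, global max over
global min, is available as an option; both agree with the published table
at printed precision); the thrombus burden as the mean of the three largest
per-frame areas in the bifurcation region (±1 SB diameter around the
ostium); and the proximal summary (min/mean/max of per-frame mean diameters,
mean lumen area with the ellipse area π·Dmax·Dmin/4 as the per-frame
default).

## Statistics

Group comparisons mirror the bench analysis: median (IQR) with type-7
(linear interpolation) quantiles, Kruskal–Wallis one-way ANOVA on ranks
with tie correction and the chi-square approximation (k−1 df), and Dunn's
pairwise z-tests on pooled rank means, run only when the omnibus p < 0.05 —
calling the post-hoc without a significant omnibus raises. Dunn p-values
are reported unadjusted *and* Bonferroni-adjusted; the source analysis does
not state an adjustment, so the unadjusted column is the default and the
ambiguity is flagged here rather than resolved. For total n ≤ 12 an exact
permutation p-value is computed alongside the approximation (rank-sum
enumeration, vectorized over the final two groups; the 5×3 case with
756,756 assignments runs in under a second, and the chi-square p agrees
with it to within 0.05 there). The chi-square test's simulated type-I error
at α = 0.05 with three groups of five is ≈0.04–0.05, inside the nominal
band.

## Synthetic cohort generator

The generator emulates what the bench study measured, not how the physics
produced it:

* **Apposition mixes** per strategy are Dirichlet-distributed around the
  normalized published median WA/MA/floating percentages — KIO
  (0.791, 0.049, 0.160), KBI (0.929, 0.033, 0.038), BD-DES
  (0.972, 0.028, 0) — with concentration 110, chosen so the simulated
  spread matches the published IQR widths (a few percentage points).
* **Thrombus severity** (the per-sample top-3 mean) follows a zero-inflated
  piecewise-lognormal calibrated by quantile inversion to each group's
  median (Q1–Q3): KIO 0.52 (0.17–0.65), KBI 0.70 (0.15–1.16), BD-DES
  0 (0–0.09) mm². The positive part is log-linear in standard-normal scores
  through the quantile knots with lognormal tails; a *single* lognormal is
  the one-segment special case, but the published KIO triple is more
  log-left-skewed (log-spacing ratio ≈5) than any single lognormal admits
  without pushing the zero atom to the 25 %-quantile boundary, where
  finite-sample quantiles of draws become degenerate. The piecewise family
  reproduces the target quantiles exactly and Monte-Carlo-stably. Zero
  medians use a zero atom ≥ 0.5 (default 0.6). Within a pullback, frame
  areas follow a fixed axial profile whose 3-frame plateau carries the
  severity exactly, so the top-3-mean statistic recovers the planted value.
* **Coating-damage counts** per category are negative-binomial (size 10)
  with the published category medians as means; zero medians stay zero.
* **Frame diameters** are drawn so the per-frame Dmax/Dmin averages the
  group's elliptical-index target (1.06/1.05/1.05) around the group's mean
  proximal diameter.

All families are modelling choices — the source tables publish only medians
and IQRs of n = 5 — and are isolated in `GroupConfig`/`CohortConfig`. One
seeded `numpy` generator drives everything: cohorts are byte-identical
under a fixed config and seed. `noise_scale = 0` collapses every
distribution to its group median, a degenerate oracle the tests exploit.
An optional hook (`thrombus_tracks_floating`, off by default) rescales a
sample's severity by its realized floating fraction, for end-to-end runs
that want the floating→thrombus direction coupled rather than planted.

What passing tests show — and what they do not: the pipeline recovers what
the generator plants (round-trips, calibrations, directions) and matches
its analytic flow oracles; it does not validate blood–device interaction,
image segmentation (measurements act on frame records, not images), or any
biological thrombosis mechanism. Thrombus is generated as data, not
computed from shear.

## Problem sizes

Chosen so a full verification pass (test-suite plus study) runs on one CPU
in tens of minutes:

* CFD cohort profile: shortened vessel (10/8/5 mm segments), 14 mm stented
  span, 32 strut cross-sections at 0.75 mm pitch; mesh `h_max` 0.34 mm,
  near-wall factor 0.65, strut surfaces capped at 0.055 mm → ~8×10³
  elements, ~4–5 s per sample.
* Reference/benchmark meshes: Poiseuille at `h_max` = width/20;
  convergence studies refine by 0.7 per level (the shipped stented example
  spans ~8.5k→21k elements); the full-length model at the reference sizing
  (~1.6×10⁵ elements) is meshed in the tests but not solved there.
* Statistics: 10,000 null replicates for the type-I check; 10⁵ draws for
  quantile calibration checks; 200 samples/group for generator round-trips.

## Known limitations

Steady (non-pulsatile) flow, rigid walls, Newtonian rheology — all
properties of the bench protocol being emulated, not approximations of it.
The 2D longitudinal cut cannot represent out-of-plane strut geometry or
true 3D ostial flow; it reproduces trends, not patient-level hemodynamics.
Strut corners are square, so the maximum shear rate retains a weak mesh
dependence concentrated at corner singularities (the thresholded *area* is
the convergent endpoint; the shipped convergence study shows <5 % change
per refinement level for it, while γ̇_max still drifts upward). Published
per-sample raw data are unavailable, so group-level distributions are
calibrated to medians/IQRs only, and published p-values are not
reproduction targets.
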