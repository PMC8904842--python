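# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind each analysis stage, what the synthetic generators do and do
not emulate, and the known limitations.

## Tensile curve parameterization

**Kinematics.** Stretch λ = (l₀ + Δ)/l₀ from jaw displacement; Cauchy stress
σ = F/(w₀·e₀)·λ under the incompressibility assumption standard for soft
tissue. Units: forces N, lengths mm, stress kPa, strain energy µJ/mm³
(numerically equal to kPa·(dimensionless stretch)). The 10 N load-cell range
and 1.5 mm/min test speed are recorded as provenance metadata in
`TensileConfig` and are not used in computation.

**Four-zone model.** Pre-rupture stress is described by a piecewise family:
linear with slope E₁ on [1, λₐ], a C¹ monotone cubic Hermite bridge on
[λₐ, λᵦ] with end slopes E₁ and E₂, and linear with slope E₂ beyond λᵦ. The
bridge endpoint value σᵦ defaults (in the generator) to the average-slope
secant σₐ + ½(E₁+E₂)(λᵦ−λₐ), which satisfies the Fritsch–Carlson
monotonicity condition for any E₂ > E₁ > 0. The transition point is defined
as the midpoint: λₜ = (λₐ+λᵦ)/2, σₜ = (σ(λₐ)+σ(λᵦ))/2.

**Zone-boundary detection.** Two stages:

1. *Expanding-window search*: on the moving-average-smoothed stress
   (window 5 samples), linear fits grow from each end of the pre-rupture
   curve; the largest prefix with R² ≥ `r2_min` (default 0.995) gives λₐ,
   the largest suffix gives λᵦ. This stage alone under-localizes λᵦ on
   steeply stiffening curves: the suffix-window variance is so large that
   the R² criterion tolerates boundary errors of ~0.3 in stretch.
2. *Curve-family refinement* (default on): for fixed (λₐ, λᵦ) the four-zone
   family is linear in (E₁, E₂, σᵦ), so the inner fit is a weighted linear
   least-squares solve and the two boundaries are found by an iterative
   grid-zoom plus a Nelder–Mead polish of the profiled residual. Residuals
   are weighted by 1/max(σ_smooth, 0.02·σ_max): arterial stress spans three
   orders of magnitude and load-cell error grows with load, so relative
   weighting keeps the low-stiffness zone and the elbow informative. On
   noise-free curves from the generator family the boundaries are recovered
   to well within the sampling grid.

Degenerate inputs: a window overlap (sharp elbow or straight line) fits the
crossing point of the two zone lines; the refinement then distinguishes a
true elbow (four-zone fit much better than one line; both boundaries set to
the elbow, flag raised) from a featureless straight line (flag raised,
boundaries at the crossing point). λᵦ is capped so the high-strain zone
retains at least `min_zone_points` samples below the stress maximum.

**Slopes.** E₁/E₂ are ordinary least-squares slopes on the raw (unsmoothed)
curve over [1, λₐ] and [λᵦ, λ@σ_max]; a concave curve (E₂ < E₁) is returned
with a warning rather than an error.

**Rupture.** A sample qualifies when stress falls below (1 − drop_frac) of
its value within the next `drop_lookahead` samples (defaults 20%, 5); among
qualifying samples the one of maximal stress is the rupture point. Without
any, the last sample is returned flagged unruptured, Eᵣ is reported as NaN.

**Strain energy.** Composite Simpson's rule on ∫σ dλ. When the curve's own
samples already form a uniform odd-count grid ending at the integration
limit they are used directly (Simpson is then exact for polynomial stress up
to degree 3); otherwise the curve is linearly resampled onto a uniform
1001-point grid. Simpson and trapezoid agree within 0.5% on smooth curves.

## Residual strain

**Pre-stretch.** λᵢ = in-situ/ex-vivo distance per adjacent marker pair
(the artery retracts on excision, so λ ≥ 1). Segments are binned into thirds
by the normalized in-situ midpoint position — boundaries at 33.3% and 66.6%,
with the narrow gap between 33.3% and 33.6% assigned to the middle third.
The ratio cancels a common µm/pixel calibration factor but not a differing
one (tested). The 15-minute viscoelastic stabilization wait is protocol
metadata, not computation.

**Opening angle.** Vertex convention: rays from the point at half the
cumulative midline arc length (the perimeter midpoint) to the two cut ends;
α is their interior angle. This gives α → 0° for an unopened ring and
α = 180° for a ring that opens flat. Other conventions exist in the
literature (e.g. the sector angle at the arc center); this one is used
consistently by the generator and the analysis, and for a noiseless arc of
central angle 2φ satisfies α = 180° − φ (the geometry oracle used in tests,
exact to <0.001° at 400 contour points). Angles above 180° are not produced
by the interior-angle definition; ring phantoms with prescribed α > 180°
are supported as contours only (the arc formula switches sign).

**Image route.** The wall band is skeletonized and the longest end-to-end
skeleton path is the midline. Skeletons retract and fork at the band's end
caps, so 0.75 of the estimated wall thickness (band area / midline length)
is trimmed from each path end and the end point is re-found by marching
along the local PCA tangent until the ray exits the band mask. Rasterized
phantoms at 4 µm/px are recovered within ~0.7°, against a 2° tolerance that
covers rasterization.

**Reliability.** Cronbach's α = k/(k−1)·(1 − Σvar(itemᵢ)/var(Σitems)) with
sample variances, computed across replicate positions over ring samples;
the alternative per-group computation is a valid re-grouping the caller can
apply by slicing the replicate matrix. α is exactly 1 for items identical up
to per-sample shifts and ~0 for independent items; it is undefined (error)
at zero total variance. With a single sample, per-sample SD is reported and
α is flagged unavailable.

## Vasoreactivity

Wall tension = force/(2·segment length); the factor 2 (two wall segments
span the myograph wires) is configurable since only the unit is fixed by
convention. Basal tension for an 80 mmHg-equivalent set point uses Laplace's
law T = P·r with 1 mmHg = 0.133322 kPa (kPa·mm ≡ mN/mm).
%Kmax = 100·(T − basal)/(Kmax − basal); %Rmax = 100·(T_pre − T)/(T_pre −
basal) after preconstriction with 10⁻⁶ M phenylephrine (protocol metadata).

The canonical model is the four-parameter logistic in log₁₀ dose with hill
slope free, fitted by Levenberg–Marquardt/TRF least squares with a
15-point multi-start grid (5 EC50 quantiles × 3 hill starts); the
convergence flag reports honestly whether any start converged.
pD2 = −log₁₀EC50 holds to machine precision by construction. Emax defaults
to the fitted top parameter ("observed max" is available by configuration).
Fits are performed on normalized responses by default (configurable to raw
tension). "Abolished response" rule: when a reference span is supplied
(100% for %Rmax data) and the fitted span is below 10% of it, the record is
flagged and pD2 withheld — mirroring the handling of a vasodilator response
that is absent in one experimental group. Group summaries report mean ± SEM,
excluding and counting non-converged fits and pD2-not-assessed records.

## Histomorphometry

**Counting protocol.** Luminance grayscale → Gaussian blur (σ = 2 px) →
automatic threshold (Otsu on ROI pixels; a fixed level is configurable) →
hole filling → Euclidean distance transform → watershed from h-maxima
markers (depth 2 px, with near-coincident plateau maxima merged by a 3-px
dilation) → particle filter to 5–200 µm². The h-maxima marker rule keeps
the single shallow ridge of an elongated nucleus as one marker while the
two distinct peaks of a touching pair (separated by a deeper saddle) remain
two. Roundness = 4A/(π·major_axis²) (1 for a disc, b/a for an ellipse),
clipped at 1 against rasterization overshoot; density = count per mm² of
ROI.

**Stain deconvolution.** OD = −log₁₀(max(I,1)/255) per channel;
concentrations c = OD·M⁻¹ with negatives clipped. The default stain matrix
pairs a hematoxylin-like dark blue-purple vector (elastin-like in an
Elastic-van-Gieson-type stain), an eosin/fuchsin-like pink vector
(collagen-like), and a neutral gray residual vector [1,1,1]/√3 — chosen
neutral rather than the orthogonal cross product because the cross product
has negative OD components and therefore cannot paint valid RGB in the
phantom; the matrix condition number is ~3. For real slides the matrix must
be measured from single-stain controls and passed explicitly. Fiber
fractions are positive-pixel area percentages at a concentration threshold
of 0.15 (the percentage is monotone non-increasing in this threshold).

**Morphometry.** Diameters from traced perimeters as d = P/π (effective
circularity); intima-media thickness (d_med − d_lum)/2, adventitia
thickness (d_adv − d_med)/2, media/lumen ratio d_med/d_lum, cross-section
area π/4·(d_adv² − d_lum²). Note the annulus formula applied to typical
rat-aorta diameters (≈1.6/2.1 mm) gives ≈1.4×10⁶ µm², an order of magnitude
above some published "cross-section area" values whose definition is
unclear; this package implements the annulus formula and makes no claim of
matching alternative definitions. Perimeter tracing thresholds the
grayscale at configurable tissue/media levels, Gaussian-smooths each mask
(σ = 2 px) and measures subpixel 0.5-level contours, keeping staircase bias
well under 1%.

## Synthetic generators

All generators are deterministic under a fixed seed and exactly invertible
by their paired analyses at zero noise.

- **Tensile**: the four-zone family above, sampled on a uniform λ grid of
  500 points (the sampling rate of real records is not constrained; 500 is
  a free default) ending 4% beyond rupture, with a post-rupture drop to 5%
  of σᵣ over 2% stretch so rupture detection has a defined cliff. Noise is
  additive Gaussian on stress by default, or proportional
  (sd = noise_sd·|σ|) with `noise_mode="relative"` — the proportional mode
  is the one under which all zones are comparably identifiable and is used
  in the recovery studies at 5%. Cohorts add a between-animal coefficient
  of variation (default 5%) on the two moduli; this is a pipeline-
  propagation setting, deliberately smaller than published between-animal
  SEMs, so that group-ordering checks probe the analysis chain rather than
  statistical power.
- **Rings**: the opened ring is a circular arc preserving the closed-ring
  midline circumference 2π·mid_radius (radius grows as the ring opens;
  180° opens to a straight strip). Rasters are rendered analytically with
  flat end caps so a narrow cut is never bridged by cap rounding.
- **Markers**: equidistant ex-vivo markers (default 10 mm spacing) and
  in-situ distances scaled by the prescribed per-segment λ.
- **Dose-response**: 4PL responses on 8 half-decade doses (10⁻⁹–10⁻³ M)
  with additive noise.
- **Histology**: an annulus (lumen / media / adventitia, medial boundary
  midway by default) with non-overlapping elliptical nuclei painted with
  the residual stain vector and fiber fractions painted pixel-exactly with
  the elastin/collagen vectors in OD space. The default 0.2 µm/px pixel
  size (a 100×-magnification scale) keeps nuclei of ~22 µm² at ≳13 px
  equivalent radius, where the blur+threshold protocol's systematic area
  bias (≈πσ² px² boundary shrinkage plus threshold placement) stays below
  5%; at coarser sampling the protocol measurably underestimates small
  objects, which is a property of the protocol, not the phantom.

What the phantoms do **not** emulate: real EVG sections have textured,
spatially correlated staining, out-of-focus blur, touching and overlapping
nuclei with varying sizes, elliptical rather than circular vessel sections,
and fibers as connected structures rather than independently painted
pixels. Nuclei-counting recovery is therefore demonstrated on fiber-free
phantoms — the protocol assumes nuclei are the dominant dark objects in the
ROI, which holds within a nuclei-selective view of a real section but not
when scattered dark fiber pixels share the histogram. Passing recovery
tests shows the protocol chain is correctly implemented and unbiased in its
validity regime; it does not certify accuracy on arbitrary real slides.

## Pipeline

`run_study` executes the enabled stages per animal over a declarative
groups × animals layout, spawning per-animal seeds from the study seed, and
aggregates mean ± SEM (SD/√n; a single-animal group reports SEM 0 with a
flag to keep tables rectangular). Relative difference between group means
is 100·(comparison − reference)/reference, reported at full precision and
rounded to integers for report text. Reports are versioned JSON with
per-parameter CSV tables and are byte-identical across reruns at the same
seed. Hypothesis testing (normality checks, ANOVA, post-hoc comparisons) is
intentionally out of scope — those are routine procedures for which
standard statistical software should be used on the exported tables.

## Known limitations

- The four-zone bridge is one convenient C¹ monotone interpolant; real
  transition-zone shapes vary, and boundary estimates on real data inherit
  whatever mismatch exists between the true elbow shape and the cubic
  bridge.
- E₁ is intrinsically unrecoverable when absolute stress noise is of the
  order of the entire low-strain stress range (e.g. 20 kPa additive noise
  against a ≤17 kPa zone-1 signal); recovery claims hold under the
  proportional noise model.
- The opening-angle image route expects a single connected band with one
  cut and a thickness small compared to the arc length; heavily jittered or
  fragmented masks are rejected rather than guessed at.
- No constitutive (hyperelastic/viscoelastic) modelling, no receptor-
  kinetics modelling, and no machine-learned segmentation — by design.
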