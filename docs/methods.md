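# Methods

This note records the models, numerical choices and open design decisions
behind `morphofit`, and what the synthetic-data tests do and do not show
about real anatomy.

## The anatomical model

The posterior rectus sheath plane (PRSP) is treated, per side, as the
**convex hull** of its boundary landmarks: the caudal xiphoid tip, the
cranial pubic symphysis tip, the linea alba points and that side's
semilunar points, with the midline landmarks (xiphoid, pubis, linea alba)
shared by both sides. This is the mathematically forced reading of a
Delaunay-triangulation-based construction — the Delaunay tetrahedralization
of a point set tessellates exactly its convex hull — and it makes every
downstream object (volume, bounding box, sections) well defined and
convex. The cost is that genuinely concave anatomy cannot be represented;
the convex hull is an upper envelope of the true plane.

Coordinates are right-handed with x = patient's left, y = anterior,
z = cranial, origin arbitrary per patient. All geometry is rigid-motion
invariant (tested), so the origin convention carries no information.

## Sectioning

A minimal-volume **oriented bounding box** is searched over candidate
orientations: one per hull-facet normal, with the in-plane orientation
refined by 2D rotating calipers, plus the three coordinate axes (which
guarantees the result never exceeds the axis-aligned box). This
facet-aligned candidate set is a standard practical relaxation of the
exact minimal box; for thin lens-like volumes the dorsal/ventral facets
dominate and the relaxation is tight in practice. Ties are broken by the
lexicographically smallest axis triple; axis signs are canonicalised, so
the box is a pure function of the geometry.

"Slices parallel to the dorsal- and ventral-most faces" is operationalised
as slicing perpendicular to the smallest-extent box axis. A runtime
warning fires if the volume is not actually thin (smallest extent not
below half the next one). The plane stack is **centred**: planes sit every
`spacing` (default 1 mm) symmetric about the mid-thickness plane. This
coincides with the convention of starting half a spacing from the dorsal
face whenever the extent is an integer multiple of the spacing, gives a
volume thinner than the spacing its mid-plane section, and — unlike a
one-sided convention — is invariant under reversal of the slicing
direction, which makes the rigid-motion invariance of the maximal slice
exact rather than approximate. Plane ∩ hull intersections are computed by
edge clipping followed by a 2D hull, so every section is a convex CCW
polygon in its own frame.

## Inscribed devices

All fitters operate on the section's edge half-planes aᵢ·x ≤ bᵢ and are
deterministic functions of their input.

- **Circle** — the Chebyshev centre: maximise r subject to
  aᵢ·c + r ≤ bᵢ, solved exactly with `scipy.optimize.linprog` (HiGHS).
- **Ellipse** — maximise log det B subject to ‖B aᵢ‖ + aᵢ·d ≤ bᵢ over the
  symmetric positive-definite shape matrix B and centre d. The program is
  convex, so the SLSQP solution from the Chebyshev-ball start (with
  analytic gradients, polygon pre-scaled to unit area for conditioning)
  is the global optimum; a returned B is always shrunk by the worst
  constraint ratio, so the reported ellipse is exactly feasible, and a
  solution that fails to dominate the feasible Chebyshev ball triggers
  one restart from a smaller interior ball. Containment is certified by
  the constraints themselves; boundary sampling is used only as a
  test-time assertion.
- **Rectangle** — maximise w·h over centre, free angle, width and height
  with all four corners inside. The fixed-angle subproblem (maximise
  log u + log v over the linear constraints aᵢ·c + pᵢu + qᵢv ≤ bᵢ) is
  convex and solved by SLSQP, then re-expanded exactly at the returned
  centre by enumerating the stationary points and vertices of the (u, v)
  feasible region. The orientation is handled by multi-start: a uniform
  angle grid (clipped to 6–24 starts of the `n_starts` budget, default
  32; remaining starts are seeded random poses derived from a hash of
  the polygon), followed by a 1-D hill-climb of the angle with step
  refinement down to ~0.1°. An `axis_aligned` flag pins the angle for
  sensitivity analysis; the default is free orientation, since nothing
  in the construction privileges the box axes. Against brute-force
  oracles on random convex polygons the fitter is within ~0.5 % of
  optimal (tested at 2 %).
- **Polygon** — "fewer than 10 sides" is read as ≤ 9 vertices. The device
  is the largest section reduced by greedily deleting the vertex whose
  removal (a chord between its neighbours) loses the least area; chords
  of a convex polygon stay inside it, so convexity and inscription are
  preserved. Greedy reduction of a 12-gon retains ≥ 95 % of the best
  9-vertex subset (tested against exhaustive search).

Per patient and side, the circle/rectangle/ellipse are fitted in **every**
section and the largest kept (ties within 1e−9 relative go to the
smaller slice index); the polygon device comes from the largest section.
The pipeline default of 4–8 rectangle starts per slice (vs. 32 for
standalone fits) is a throughput choice; the orientation grid plus
hill-climb keeps the gap to the full budget well under the testing
tolerances.

Numerical tolerances: containment 1e−6 mm; area/volume identities 1e−9
relative; degenerate sections (area below tolerance) are rejected.

## Dose model

One islet equivalent (IEQ) is the volume of a perfect 150 µm-diameter
sphere, V_IEQ = πd³/6 ≈ 1.76715×10⁻³ mm³. A device of footprint area A
(mm²), thickness τ = 0.6 mm and islet volume fraction φ = 0.10 holds
φτA / V_IEQ islets, i.e. a **footprint dose density** of
φτ/V_IEQ ≈ 33.95 IEQ mm⁻². The corresponding per-mm³ density
(φ/V_IEQ ≈ 56.6 mm⁻³) is exposed as `volumetric_dose_density`; the
headline constant in the source material is only consistent with the
footprint basis, which is what the pipeline uses. Patient dose sums the
left and right fitted areas (two devices), divides by body weight, and
compares the unrounded IEQ kg⁻¹ against the 10 000 IEQ kg⁻¹ therapeutic
threshold. A missing body weight yields an *unavailable* dose, never
zero.

## Screening models

Features: age (years), sex (female 0 / male 1 — two levels, no one-hot),
BMI (kg m⁻²) and five distances (mm): ASIS–ASIS, xiphoid–pubis, body
depth, width, circumference at L4. Patients missing any feature are
excluded up front (complete-case analysis).

- **Regression**: support-vector regression with a degree-2 polynomial
  kernel ("quadratic SVM" in common tool parlance), γ = 1/p, coef0 = 1.
  Features are z-scored and the response is z-scored **inside each
  training fold**; the box constraint C = 1 is therefore in units of the
  response SD (an unscaled C = 1 on mm²-scale responses would underfit
  structurally), and ε uses the IQR/13.49 heuristic on the standardized
  response. Metrics (R² = 1 − SSE/SST, RMSE, MAE in mm²) are computed on
  pooled out-of-fold predictions from seeded, shuffled 10-fold CV. A
  leakage test pins that fold standardization never sees held-out data.
- **Classification**: quartile bands of the response (edges at the
  25/50/75th percentiles, linear interpolation; a value equal to an edge
  joins the band above, so the ≥75th band is closed below). SVM with a
  Gaussian kernel; the named presets map to kernel scale √p ("medium")
  and 4√p ("coarse"), i.e. γ = 1/p and 1/(16p) on standardized features,
  C = 1, stratified 10-fold CV. Reports: pooled confusion matrix,
  accuracy, one-vs-rest ROC/AUC per class on out-of-fold decision
  values, with the hard classifier's (FPR, TPR) as operating point. On
  ordered synthetic responses the outer bands (<25th, ≥75th) carry the
  highest AUC — the expected geometry of thresholded continua.

## Cohort statistics

Shapiro–Wilk normality is recorded per group (not assessable below n = 3)
but never switches the test: comparisons are Mann–Whitney U (two groups;
exact/asymptotic selectable), Kruskal–Wallis (more), with **Dunn's**
pairwise z-tests on pooled ranks (tie-corrected) and Bonferroni
adjustment — the adjustment method is configurable since the convention
is not fixed in the field. Paired left/right data use the Wilcoxon
signed-rank test with zero differences dropped; an all-zero difference
vector short-circuits to p = 1 with a flag. Age bands are half-open
[0, 18), [18, 45), [45, ∞) — resolving the overlap of the conventional
"0–18 / 18–45" labels at 18 — and BMI bands follow WHO cut-points.
Strata report mean ± SD even though the tests are rank-based, matching
how such cohorts are conventionally tabulated. Under the null the tests'
type-I error at α = 0.05 is calibrated to [0.035, 0.065] over 1000
simulations (tested).

## Synthetic cohort generator

The generator replaces a non-deposited 642-patient CT reference cohort
(47.35 % female). What it reproduces, and how:

- **Demographics** — per-sex truncated-normal marginals for age, BMI,
  height, weight and the five distances, anchored to the published
  means ± SDs. Truncation is mean ± 3 SD, tightened by physical floors
  (e.g. weight ≥ 20 kg, BMI ≥ 13); floors make some truncations
  asymmetric, so realism tests compare sample means against the
  *analytic truncated-normal mean* rather than the raw location
  parameter. Joint structure is a Gaussian copula: size variables share
  pairwise correlation 0.5, age correlates 0.25 with size — documented
  constants, since only marginals are published. BMI is sampled as its
  own marginal and is therefore not exactly weight/height²; records are
  internally consistent but not arithmetically exact, like real charts.
- **Xiphoid–pubis distance** — the published table entry for this field
  (~53/72) is implausible as mm next to the other mm-scale distances;
  the generator instead uses ~340 mm (female) / 360 mm (male) ± 30 mm,
  an anatomically plausible adult sternum-to-pubis span, and this drives
  trunk length.
- **Landmark geometry** — stations every 30 mm (margin 15 mm) between
  pubis (z = 0) and xiphoid (z = L). The linea alba bulges ventrally by
  D·sin(πt); the semilunar points sit at lateral offset
  w(t) = W·(4t(1−t))^0.5 — an elliptical, bluntly tapering semilunar
  line — and at 15 % of the midline bulge height. The enclosed hull is
  then a thin lens whose thinnest box axis is dorsoventral. The
  elliptical taper is a deliberate choice: it reproduces the reported
  qualitative area ordering (ellipse > rectangle > circle), whereas
  pointier leaf profiles produce near-trapezoidal sections in which
  rectangles beat ellipses. No published geometric summary of
  semilunar-line curvature exists to validate either choice; this is a
  stand-in, not an anatomical model.
- **Size scaling** — W scales with body width, D with body depth and
  (BMI/26.3)^0.4, capped at 0.45·W to preserve the thin-volume
  guarantee; PRSP volume therefore rises across BMI bands, matching the
  reported direction. Isotropic Gaussian landmark noise (SD 1 mm)
  emulates CT click error.
- **Defaults** — W = 80 mm and D = 22 mm give per-side volumes of
  ~0.2–0.5×10⁶ mm³ and polygon-device areas ~1.5×10⁴ mm², the right
  order of magnitude for the published cohort; cohort-level absolute
  means are *not* calibrated to the original data and are not claimed.

What passing tests show: the pipeline's geometry, optimisation,
dose arithmetic, models and statistics behave correctly on anatomy-like
inputs with the study's qualitative structure. What they do not show:
agreement with any real patient's PRSP, the original cohort's absolute
volumes/areas/attainment rates, or regression/classification accuracy on
real anatomy (the synthetic response surface is cleaner than nature).

## Exact-answer fixtures

Boxes (w × h × t) and convex prisms provide closed-form ground truth for
every geometric stage: hull volume w·h·t, largest slice w × h, incircle
radius min(w, h)/2, maximal rectangle w·h, maximal ellipse πwh/4;
triangles add the incircle formula r = (a + b − c)/2 and the Steiner
inellipse (area ratio π/(3√3), the maximum-area inscribed ellipse of any
triangle).

## Problem sizes

The default test run fits ~50 random polygons against brute-force
oracles, a 200-patient cohort end to end for the ordering checks
(rectangle budget 4 starts/slice there), and 1000 null replicates for
test calibration. These sizes were chosen so the whole suite completes in
roughly a quarter hour on a single core while keeping every statistical
assertion at ≥ 3σ separation from its failure boundary.

## Known limitations

- Convexity: concave PRSP regions are over-covered by the hull; fitted
  areas are upper bounds with respect to the landmark envelope.
- Frontal sections only: a differently oriented plane could admit a
  larger device; the restriction follows the source construction and is
  also the clinically meaningful orientation.
- The minimal bounding box is facet-normal exact, not O'Rourke exact.
- The dose model ignores oxygenation, islet viability kinetics and
  device stacking.
- Screening metrics on synthetic cohorts do not transfer to real
  populations; the models are mechanics, not claims.
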