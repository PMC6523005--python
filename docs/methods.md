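# Methods

## Scope

`radqc` implements the quantitative analyses behind two radiographic
quality-control procedures:

1. **Beam-quality characterization of a printed plastic absorber** —
   extracting the half-value layer (HVL), half-value density (HVD) and
   linear attenuation coefficient of polylactic acid (PLA) from air-kerma
   transmission measurements across tube voltages, plus the tube-voltage
   trend and the cross-material relation to the beam's aluminum HVL.
2. **Perpendicular-ray localization** — recovering the point where the ray
   from the x-ray focal spot meets the image receptor at 90°, from the
   projected images of vertically aligned fiducial-marker pairs on a
   printed test tool.

A seeded synthetic-data module emulates both bench experiments with known
ground truth.

## Transmission model and HVL extraction

A radiographic beam is polyenergetic. Narrow-beam transmission through a
thickness *t* of absorber is a weight-sum of exponentials over the photon
spectrum; as low-energy photons are removed preferentially, the local
effective attenuation rate −d(ln T)/dt decreases with depth (beam
hardening), so a single exponential underfits measured curves. The analysis
therefore fits a two-term ("second order") exponential decay to the
repeat-averaged air-kerma rate K̄(t):

    K(t) = a1·exp(−m1·t) + a2·exp(−m2·t),   a_i, m_i ≥ 0.

Fitting choices:

* **Averaging before fitting.** Repeats at each thickness are averaged
  arithmetically and the 4-parameter model is fit to the mean curve.
* **Bound-constrained least squares** (trust-region reflective) with
  non-negativity on all four parameters; tolerances 1e-14.
* **Multi-start.** Starting values come from a log-linear single-exponential
  fit; its rate is split into a fast/slow pair and scaled by {0.5×, 1×, 2×};
  the lowest-SSR start wins. This makes the fit robust to the shallow
  likelihood valley along m1 ≈ m2.
* **Canonical ordering** m1 ≥ m2 so (a1, m1) is always the fast component;
  reported parameters are reproducible across starts.
* **Convergence flag.** `converged=False` when the fit RMSE exceeds 5% of
  the fitted zero-thickness value a1+a2. A constant (non-attenuating) curve
  fits with m1 = m2 = 0 and is rejected downstream by the HVL solver.

The HVL is the thickness at which the fitted curve reaches half its
**fitted** zero-thickness value (a1+a2)/2, found by bracketed root-finding
to |Δt| < 1e-9 in the fit's abscissa unit. Using the fitted rather than the
measured t = 0 reference makes the estimate insensitive to noise in the
single unattenuated reading; the measured-reference alternative is available
through `solve_hvl(..., reference_value=...)`. HVLs are computed on the
**nominal** thickness axis (cm, reported in mm); caliper-measured thickness
enters only through the areal density.

The attenuation coefficient is μ = ln 2 / t½ — equal in magnitude to
ln(0.5)/t½ and reported positive by convention.

## Half-value density

The HVD re-expresses the 50% point as areal density (g/cm², mass per face
area), which removes the physical-density dependence of HVL and isolates
composition effects. Implementation: the averaged curve is refit against
cumulative areal density ρ(t) = (t / t_article)·σ_article, where σ_article
is the per-article areal density from the metrology module
(mass ÷ length ÷ width), and the 50% point is solved exactly as for HVL.
For articles of uniform areal density this equals the nominal scaling
HVL_cm / t_article_cm × σ_article to high precision (the dual-path agreement
is asserted at 1e-6 relative in the tests).

## Trend and cross-material fits

* HVL or HVD vs tube voltage is fit with an unweighted ordinary-least-squares
  quadratic y = a·kV² + b·kV + c (no weighting is assumed).
* Specimen HVL (mm) vs the dosimeter-reported aluminum HVL (mm) is fit with
  an unweighted OLS line. When this fit is run on the published
  beam-quality table it reproduces the published slope/intercept only to
  ~1–2% because the table prints rounded inputs while the original fit used
  unrounded measurements; the same rounded-input effect can move a recomputed
  μ across a 3-s.f. rounding boundary (it does so for exactly one of the 16
  reference entries, 110 kV aluminum).

### Reference beam-quality data

The package bundles the published per-kV reference values for **clear
(natural) PLA only** — specimen HVL 20.1→27.0 mm and aluminum HVL
2.6→6.2 mm over 50–120 kV, with mean areal density 0.590 g/cm² per 0.5 cm
article. Per-kV HVLs for the **green** PLA filament were never published
(only its 50 and 120 kV endpoints and trend coefficients), so the green
trend rows cannot be independently reproduced and no green per-kV data
ships with the package. This is a limitation of the available data, not of
the method: the same pipeline applies to any filament once its transmission
table is measured.

## Synthetic transmission experiments

`beam_sim` emulates the bench protocol: nominal thicknesses 0–5 cm in
0.5 cm steps, tube voltages 50–120 kV in 10 kV steps, three repeats per
point. Its components:

* **SpectrumModel** — a discrete effective spectrum: components
  (weight, μ_specimen per-cm, μ_aluminum per-mm). A two-component model
  yields exactly double-exponential transmission and strictly decreasing
  effective attenuation, i.e. beam hardening of the same functional form the
  analysis fits. The default per-kV models are equal-weight two-component
  mixtures with hard/soft rate ratio 2.5, calibrated by root-finding so each
  kV's exact specimen and aluminum HVLs equal the bundled clear-PLA
  reference values (simulated HVLs span ~20–27 mm).
* **Noise** — multiplicative Gaussian on each reading:
  K = K₀·T(t)·(1+ε), ε ~ N(0, cv). Dosimeter readings are positive with
  roughly constant relative error; draws with ε < −0.99 are resampled so
  readings stay strictly positive. The repeat-to-repeat variability of the
  instrument is not published; the default cv = 0.01 is a stated guess,
  realistic for a reference-class solid-state dosimeter.
* **Ground truth** — the exact HVL of each model is obtained by bisection on
  the transmission curve (not from the fit), giving an independent oracle
  for round-trip tests.
* **Seeding** — one global seed splits into keyed `SeedSequence` substreams
  per tube voltage (and per marker in scenes), so simulating a subset of
  kVs reproduces exactly the draws the full protocol would give those kVs.
* **Default zero-thickness kerma rate 30 mGy/min** — a typical fluoroscopic
  entrance-rate magnitude; it cancels out of every derived quantity.

What the simulator does **not** model: tube physics (kVp waveform, anode
angle, filtration), scatter, detector energy response, thickness or
density variation between articles, and dosimeter energy dependence.
Passing round-trip tests therefore demonstrates correctness of the fitting
and solving machinery under the stated noise model, not robustness to every
systematic error of a real bench.

## Perpendicular-ray geometry

The test tool is a 10 cm square, 20 cm tall platform with radiopaque marker
pairs aligned vertically at its four corners and a single fiducial at the
top center. For a point source, the projections of the two markers of a
vertical pair and the foot of the perpendicular from the source are exactly
collinear — a similar-triangles identity that holds for any source-image
distance (SID) and any tool placement. Each pair thus contributes a
detector-plane line through the perpendicular ray; two non-parallel pairs
determine it, and four over-determine it.

Estimators (both purely 2-D; marker heights never enter the inverse
problem):

* **least_squares** (default): the point x minimizing Σᵢ dist(x, lineᵢ)²,
  solved in closed form from the normal equations
  Σᵢ (I − dᵢdᵢᵀ)(x − pᵢ) = 0. Degenerate (all directions equal) geometry is
  detected by rank; near-parallel but distinct lines still solve.
* **pairwise_centroid**: every line pair with crossing angle > θ_min
  (default 0.5°) is intersected and the centroid of the intersection cloud
  returned — the numerical analogue of the manual draw-lines-and-mark-the-
  overlap procedure on a PACS workstation. Retained for fidelity to
  practice; under localization noise its median error is never better than
  the least-squares estimate (asserted over seeded replicates).

Both methods agree to 1e-9 mm on noiseless input. A pair whose two
projections coincide within ε_sep = 0.05 mm is flagged on-axis: the shared
point itself estimates the perpendicular ray.

Deviation distances (to the detector center, light-field center and central
ray) are plain Euclidean distances to caller-provided reference points —
locating those references (collimator crosshair, central fiducial) is a
manual step of the physical procedure.

`estimate_sid` inverts the top-square magnification m = SID/(SID − h) to
SID = h·m/(m − 1); it is diagnostic plumbing, not part of the localization,
which is SID-independent by construction. With fewer than four top markers
the pairwise spacing is assumed to be an adjacent-corner side.

Scene-simulator specifics: detector plane z = 0 (x/y in mm), source at
height SID above its foot point; bottom markers default to 2 mm above the
detector (a thin base plate; the physical offset is unspecified, and it is
exposed in `SceneConfig`); localization noise is an independent Gaussian
per projected coordinate (default sd 0, typical test value 0.3 mm ≈ 2 px at
0.143 mm pixel spacing).

## Metrology statistics

Areal density is mass ÷ (length × width) per article. Summaries report
mean ± sample standard deviation (n−1 denominator, the convention for
small-sample "± 1 SD" reporting). The filament-diameter comparison uses
Welch's unequal-variance two-sided t test — the test actually used for the
published comparison is unnamed, so this is an assumption; consequently the
published P-values (0.003 for diameters, <0.001 for areal densities) are
not reproduction targets, since the raw readings are unpublished. Degenerate
identical zero-variance samples report p = 1 with a warning instead of NaN.

## Problem sizes used in validation

The validation suite and the reproduction script use: full-protocol
simulations (8 kV × 11 thicknesses × 3 repeats) for round trips; 200 seeded
replicates for the noisy HVL-error statistic; 1000 randomized noiseless
scenes for the collinearity/recovery property; and 500 seeded noisy scenes
(sd 0.3 mm) for the estimator comparison — sizes chosen to make the Monte
Carlo statistics stable at a few-percent level while keeping a full run in
the tens of seconds.

## Known limitations

* The double-exponential model is an effective description; for very soft
  or heavily filtered spectra more terms may be needed, and extrapolation
  beyond the measured thickness range is unreliable.
* The cross-material line and quadratic trend are empirical interpolations
  over 50–120 kV; they carry no physical meaning outside that range.
* Fit uncertainty is summarized only by RMSE; no parameter covariance or
  propagated HVL uncertainty is reported.
* Marker centroids are assumed already digitized; no image processing or
  DICOM handling is included.
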