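# Methods

This note documents the models, algorithms, defaults and limitations of
`circumkin`, in the order data flows through the pipeline.

## Stereo reconstruction

**Camera model.** Pinhole projection with Brown–Conrady distortion, three
radial (k1–k3) and two tangential (p1, p2) coefficients — the convention
of common calibration tools; unavailable coefficients default to 0. Pose
maps world → camera as `x_cam = R·x_world + t`, world units mm. Pixel
convention: origin top-left, x rightwards, y downwards, pixel centres at
integer coordinates. Calibration is an *input* (an INI-style text file,
one camera per section); estimating it is out of scope.

**Undistortion** inverts the distortion by fixed-point iteration
(tolerance 1e-12, max 50 iterations; failure raises an error naming the
pixel). With all coefficients zero it reduces to
`((u − cx)/fx, (v − cy)/fy)`.

**Triangulation.** Per shared frame, homogeneous DLT on the two
undistorted rays; the SVD's conditioning and the inter-ray angle
(threshold 1e-6 rad) flag degenerate frames as missing. Identical camera
centres raise a degenerate-geometry error. Frames missing in either
camera are dropped and logged, never interpolated (interpolation is a
deliberate non-feature: at 3-minute sampling a gap is real information).
An optional Gauss–Newton refinement minimizes pixel reprojection error;
it is off by default because the linear solution is already exact in the
noise-free regime and the refinement mainly matters for gauge-exactness:
the algebraic DLT objective is not exactly invariant under a joint rigid
remap of cameras and scene, the refined solution is. Per-frame
reprojection residuals (mean over the two cameras, px) are stored on the
trajectory and summarized by `reprojection_report`.

With the default synthetic rig (45 cm baseline, ~1.1 m working distance,
full-HD, fx = 1400 px) the noise-free render → triangulate round trip
reproduces trajectories to ~1e-12 mm, and 1 px of pixel noise gives a
median 3D error of a few tenths of a millimetre — comparable to a
per-frame nonlinear reprojection minimizer (checked by Monte-Carlo in the
test suite).

## Trajectory representation

A `Trajectory3D` is a strictly increasing, constantly spaced time grid
(minutes; default dt = 3 min, i.e. 0.0056 Hz) with (n, 3) positions in
mm, optional onset/offset frame annotations and optional residuals. The
movement window [onset, offset] is a **required annotation** for real
data — in the source protocol onset (tendrils begin to develop) and
offset (tendrils begin to wrap, or the frame before a fall) were defined
visually from the video. A speed-threshold auto-detector (speed above 5%
of maximum for 3 consecutive intervals) is provided for synthetic
convenience only.

## Kinematic variables

* **Movement time** = (offset − onset) × dt.
* **Velocity** by forward finite difference on raw, unsmoothed positions
  (`speed_i = |p_{i+1} − p_i|/dt`); smoothing is available but off by
  default since the source analyses give no indication of smoothing.
  Average velocity is the mean speed over the whole movement window (not
  only inside detected cycles — an undocumented choice in the source,
  resolved here toward the simpler reading).
* **Peak-velocity time** = 100·(t_peak − t_onset)/(t_offset − t_onset),
  ties broken by *first* occurrence (a convention; constant-speed
  segments therefore yield 0%).
* **Cycle segmentation.** The original studies used ad hoc tracking
  software whose cycle rule is undocumented; the operational definition
  here is: one cycle = one 2π accumulation of the unwrapped polar angle
  of the detrended planar signal. Steps:
  1. Estimate the growth axis. The naive choice (first principal
     component of the positions) fails for planar, zero-growth
     oscillations, where the principal direction lies *inside* the
     oscillation plane. Instead: the linear time-trend direction of the
     positions when the trend span dominates the residual spread (>2×),
     otherwise the smallest-variance principal axis (the oscillation
     plane's normal), with a vertical fallback for degenerate inputs.
  2. Project positions onto the plane orthogonal to the axis.
  3. Subtract a centred moving-average trend. Window = one coarse period,
     estimated from the dominant peak of the summed FFT power of the two
     planar coordinates (a peak must exceed 5× the median non-DC power;
     otherwise a logged 10-frame fallback window is used). Where the full
     window does not fit (the ends), the trend is extended linearly from
     the adjacent interior — plain edge-shrinking windows bias the trend
     at the ends and shift the first/last cycle boundaries by 1–2 frames.
  4. Unwrap the polar angle; apply a monotone (running-max) envelope so
     noise jitter cannot re-cross a boundary.
  5. Boundaries at each multiple of 2π (tolerance 1e-6 rad). A trailing
     partial revolution is reported as a fraction of a turn but excluded
     from the cycle count, duration and length — the conservative reading
     of "complete a single circumnutation".
* **Cycle length** = maximum pairwise 3D distance among the cycle's
  sampled points (exact O(n²); ~30 points per cycle at 3-min sampling).
  A planar-projection variant is available (`planar_lengths=True`); 3D is
  the default since the source does not specify.

On noise-free synthetic input every metric matches its closed form to
1e-6 relative (circle chord speed `2r·sin(π·dt/T)/dt`, ellipse max chord
2a, exact cycle counts and durations); under noise of 10% of the major
amplitude the cycle count stays within ±1 of programmed in ≥95% of
seeded runs.

## Mixed-model analysis

Per metric: `metric ~ condition + (1 | plant)`, REML (the convention of
the R `lmer` default; ML by flag), condition treatment-coded with US as
reference. The REML fit is statsmodels' `MixedLM`; everything downstream
is computed here from the estimated variance components (σ²_plant,
σ²_resid) and the design matrix:

* **Coefficient covariance** Φ = (XᵀV⁻¹X)⁻¹ with
  V = σ²_plant·ZZᵀ + σ²_resid·I (GLS at the REML estimate, matching
  `lmer`).
* **Type-III Wald χ²**: intercept (1 df) and the joint 3-df condition
  term from Φ; with treatment coding and a single factor this matches
  `car::Anova(type = 3)`.
* **Nakagawa–Schielzeth R²**: marginal = varF/(varF+σ²_plant+σ²_resid),
  conditional = (varF+σ²_plant)/(same), varF the sample variance (n−1
  denominator) of the fixed-effect fitted values.
* **Contrasts**: all six pairwise differences of model-based condition
  means. Satterthwaite df = 2g²/Var(g) with g = cᵀΦc; Var(g) by the delta
  method using the *observed* information of (σ²_plant, σ²_resid) — the
  negative Hessian of the restricted log-likelihood at the optimum, by
  central differences — which reproduces `lmerTest`'s fractional dfs
  (expected information is the fallback at boundary fits). Tukey
  adjustment uses the studentized range with k = number of conditions
  (`P(q_{k,df} > |t|·√2)`), the `emmeans` default; `adjust="none"` gives
  plain two-sided t p-values.
* **Kenward–Roger** (`df_method="kenward_roger"`) applies the
  small-sample adjusted covariance Φ_A (the linear-variance-structure
  form, in which the second-derivative terms vanish) and the
  Satterthwaite-style df on the adjusted variance. For 1-df contrasts
  this is the standard first-order KR approximation; published fractional
  dfs computed with KR may require it to match exactly. Satterthwaite is
  the default.

Boundary fits (plant variance estimated at zero) are returned with a
`singular` flag and a warning, not an error; with σ²_plant = 0 the fit,
SEs and contrasts reduce to pooled OLS. The test suite cross-checks
estimates, SEs, Satterthwaite dfs and Tukey p-values against
`lmerTest` + `emmeans` on an unbalanced fixture (agreement: estimates to
1e-5, dfs to 2%).

Significance threshold α = 0.05 throughout.

## Synthetic data

The generator emulates the study conditions, not tendril biomechanics:

* **One trajectory** = start + growth·t·ẑ + drift(t) + ellipse(a, b,
  2πt/T + φ₀) + isotropic Gaussian noise, sampled every 3 min. The
  ellipse lies in the plane orthogonal to a fixed vertical growth axis —
  the simplest oscillator consistent with observed tendril paths. Drift
  moves toward a support point at a constant rate (0 = support not
  perceived), capped at the target. A fall truncates the trajectory at
  `fall_time` (the movement offset is the last pre-fall frame) and
  appends a three-frame rapid drop; falls in the source data are
  described only qualitatively, so the drop is schematic.
* **Condition presets** (US/LS/IS/DS) encode the *sign structure* of the
  observed condition differences — US faster and shorter-lived than LS,
  IS/DS intermediate — and the observed clasp fractions (13/13, 3/13,
  0/13, 8/13). The published per-condition metric magnitudes are mutually
  inconsistent under any constant-oscillator model (movement time ≈
  n_cycles × cycle duration cannot reproduce all printed differences
  simultaneously), so preset periods/amplitudes are compromise values:
  US T=80 min a=30 b=20 mm, LS T=150 a=25 b=15, IS T=140 a=28 b=18,
  DS T=110 a=26 b=17, noise 0.8 mm. Exact value-level reproduction is
  only meaningful against the archived per-observation records, which
  `io.read_records` ingests via a column mapping.
* **Record-level experiments** (`simulate_experiment`) generate the six
  metrics directly: baseline + condition shift + plant random intercept +
  residual. Default shifts mirror the published contrast signs and rough
  magnitudes (e.g. US−LS = +1.95 mm/min on average velocity); default SDs
  are plausible for the metric scales (e.g. residual 0.75 mm/min on
  velocity, chosen so a 13-plant/condition design yields contrast SEs of
  a few tenths of mm/min). Observations per plant defaults to 2: the
  source design implies ~2.2 observations per plant (115 observations
  over 52 plants) without stating the observational unit, so it is an
  explicit free parameter.
* **Trajectory-level studies** (`simulate_study`) additionally jitter
  each plant's amplitudes/rates (10% lognormal) and period (8%) — the
  trajectory-level analogue of a plant random intercept.
* **Random streams**: one `default_rng([seed, condition, plant])` stream
  per plant, so enlarging an experiment never perturbs existing plants;
  all runs are bit-reproducible given the seed.

What passing tests on synthetic data do **not** show: robustness to
tracking artefacts (marker drift, occlusion, manual re-annotation),
non-stationary circumnutation (period/amplitude evolving as the plant
grows), non-elliptical or figure-eight oscillation shapes, or the
behaviour of the cycle detector on movements with long stationary bouts.
Those need real recordings.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to bound Monte-Carlo error at
the precision being asserted: 200 seeded runs for noisy cycle recovery,
500 replicates (6 plants/condition) for type-I-error calibration, 50
plants/condition for contrast recovery (2-SE band), 100/condition for
variance-component recovery (20% band), and for the R² partition check a
mean over 5 replicate experiments at 200 plants/condition — a single
replicate's R² estimate carries MC sd ≈ 0.025, too coarse for a ±0.03
assertion. Fixed-point undistortion tolerance 1e-12; DLT conditioning
threshold 1e-12 on the singular-value ratio; REML via statsmodels'
default optimizer with a Powell fallback; numeric Hessians use relative
central-difference steps of 1e-4.

## Known limitations

* The 2π-phase cycle definition is this package's operationalization;
  other rules (peak-to-peak on a projected coordinate, zero-crossings)
  would shift cycle boundaries on irregular movements.
* Kenward–Roger dfs are first-order (exact for the implemented 1-df
  contrasts within the KR1 approximation), not the full multi-df KR
  F-statistic machinery.
* Published contrast tables occasionally show estimate/t-ratio sign
  inconsistencies (e.g. a positive estimate with a negative t); the
  package flags nothing automatically — comparisons against archived
  tables should check `t ≈ estimate/SE` first.
* The stereo stage assumes synchronized cameras and a shared frame
  clock; synchronization errors masquerade as triangulation noise.
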