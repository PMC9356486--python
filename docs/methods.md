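# Methods

## The measurement

`camhip` measures the **alpha angle (AA)** of a hip from a 65-point planar
outline of the proximal femur, the landmark scheme produced by
statistical-shape-model annotation tools on AP pelvic radiographs or DXA
images. The construction:

1. **Head circle.** A circle of best fit is placed through the femoral-head
   landmarks (indices 19–32, 0-based). The fit minimises the sum of squared
   *orthogonal* distances — an algebraic (Kåsa) linear solve provides the
   initial centre/radius, then damped Gauss–Newton refines it (update
   tolerance 1e-10, ≤100 iterations). Kåsa alone is biased toward small
   radii on short noisy arcs; the geometric refinement removes that bias.
   Near-collinear landmark sets (smallest normalised singular value
   < 1e-8) raise a degenerate-geometry error.
2. **Neck midpoint.** The two femoral-neck contour segments (indices 2–15
   medial, 37–49 lateral) are linearly densified (default 8 subdivisions
   per edge, because the narrowest section lies between contours, not
   necessarily between raw landmarks) and the closest cross-segment pair is
   found exhaustively; ties resolve to the first pair in segment order. The
   pair midpoint is the neck midpoint.
3. **Departure point.** Walking the contour from the last head-arc landmark
   toward the lateral neck, the departure point is where the distance from
   the circle centre first crosses `radius × (1 + tol_frac)` (default
   `tol_frac` = 0.25% of the radius), interpolated to the exact chord
   crossing of the tolerance circle. The crossing must be *sustained* by
   the following contour point, so an isolated sub-pixel jitter excursion
   on the head arc cannot masquerade as the head/neck junction. If the
   contour never leaves the tolerance circle the hip gets a `no-departure`
   QC flag, an undefined alpha, and is excluded from association analyses
   (complete-case).
4. **Alpha angle and cam.** AA is the unsigned angle at the circle centre
   between the rays to the neck midpoint and to the departure point, in
   [0°, 180°]. **Cam morphology is AA ≥ 60°**, boundary inclusive.

Only relative distances and angles enter, so the measurement is invariant
to rigid motions, uniform scaling, the y-axis convention, and (after side
normalisation, a mirror about a vertical axis) to laterality. Angles are
reported to 1 dp in output tables; internal precision is full double.

The departure tolerance, interpolation rule, sustained-crossing guard and
traversal direction are this package's own numerical choices (the published
description specifies only the geometric construction); all are exposed in
`MeasureConfig`.

## Synthetic outlines

`synthetic.generate_outline` builds an analytic contour in the landmark
scheme's index layout: a circular head of radius *R* (default 30 units), a
neck channel of width *w* (default 20) symmetric about the neck axis with a
gentle quadratic flare (so the narrowest section is unique and its midpoint
lies exactly on the axis, making the analytic alpha exact), and optionally
a cam bump of amplitude *A* (default 3) that leaves the circle at
`cam_onset_deg` and grows linearly over a 10° ramp. With `A > 0` the
analytic alpha *is* the onset angle; with `A = 0` it is the tangent
departure of the neck channel, `asin(w/2R)`. Landmarks are placed densely
around the junction (one exactly at the onset), so the measured departure
interpolates within ~0.3° of truth — the residual is the systematic
tolerance-crossing offset, well inside the 1° validation band. Isotropic
Gaussian jitter (seeded) emulates annotation noise.

What this bench does *not* emulate: real radiographic projection, rater
correction behaviour, osteophyte interference (excluded upstream during
point placement in the real workflow), or anatomical shape variation beyond
the parameterised family. Passing the recovery grid therefore certifies the
geometry code, not the clinical validity of AA on any given radiograph.

## Synthetic cohorts

`synthetic.generate_cohort` emulates the *structure* of a high-bone-mass
(HBM) family cohort: each of `n_individuals` (default 352) contributes two
hips. Defaults follow the published cohort's demographics: 66.7% female,
66.5% HBM, age 61.6 (SD 11.8) years, sex-conditional height/weight chosen
to reproduce the overall means (~167.7 cm, ~83.4 kg), and adolescent-sport
categories (0–1, 2–3, 4–7, >7 h/week) at frequencies 11/29/24/36%.
L1/total-hip Z-scores are drawn consistently with the HBM rule (Z ≥ +3.2 at
one site with ≥ +1.2 at the other). Per-hip cam follows a logistic model
(default intercept −2.05, male coefficient +1.55, giving ~20% cam
prevalence with a male excess); alpha angles are drawn consistently with
cam status around the cohort-typical mean.

OA is generated from a **conditional logistic model with a shared
per-individual normal random intercept** (default sd 1 — the cohort's true
left–right correlation is unknown, so this is a free, exposed choice):
`logit P(OA) = −1.95 + log(3)·cam + u_i`, giving ~20% OA prevalence.
Subphenotype grades (osteophyte, JSN, sclerosis, cyst; 0–3) come from
proportional-odds cutpoints on the same linear predictor, with cutpoints
set to the cohort-typical prevalences (~67/22/5%), then reconciled with the
Croft rule (grade ≥ 3 iff at least two features present). Follow-up is
missing-completely-at-random retention (default 33%) with monotone
non-decreasing Croft under a Bernoulli progression model.

**Marginal oracle.** GEE estimates a *population-averaged* effect; the
conditional odds ratio of the generator is attenuated toward 1 by the
random intercept (non-collapsibility). `marginal_or_oracle` integrates the
intercept out by Gauss–Hermite quadrature (96 nodes) at fixed covariates
and returns the implied marginal OR — e.g. conditional OR 2 with sd 1
implies marginal OR 1.821. This makes GEE recovery a well-posed test.

## Statistics

- **Crude OR** (`ad/bc`) with Wald CI `exp(log OR ± z·√(1/a+1/b+1/c+1/d))`
  and two-sided Wald p. Zero cells are a hard error; the Haldane–Anscombe
  +0.5 correction must be requested explicitly so that silent corrections
  never contaminate oracle comparisons.
- **GEE logistic** with independence or exchangeable working correlation
  (exchangeable default; either yields consistent point estimates), the
  moment estimator of the common correlation from Pearson residuals, and
  the cluster-robust sandwich covariance. Convergence: max |Δβ| < 1e-8
  within 100 iterations, reported honestly (`converged` flag); |β| > 30
  raises a separation error. For an unadjusted binary exposure under
  independence the score equations coincide with ordinary logistic
  regression, so the point estimate equals the crude OR for *any* cluster
  assignment — the equivalence chain used throughout the tests. In
  simulation (two hips per individual, 1000 individuals, 200 replicates)
  the robust 95% intervals cover the marginal-oracle log-OR at ~95%
  (95.2% over 600 replicates), and the mean estimate is unbiased within
  Monte-Carlo error.
- **Agreement**: Cohen's kappa on binary cam classifications, Lin's CCC
  (population 1/n moments) and Pearson's r on the angles, as used to
  validate semi-automatic against manual AA measurement.
- **Classical tests**: Pearson chi-squared (no continuity correction),
  unpaired t (pooled Student by default, Welch by flag), one-way ANOVA —
  implemented from their defining formulas and cross-checked against scipy
  in the tests. No multiple-testing adjustment anywhere (raw p-values are
  reported, matching the analysis design this mirrors).
- **Per-SD odds ratios**: BMD exposures are standardised with the sample
  (n−1) SD computed on the analysis sample.

## Pipeline conventions

- HBM: `(L1 Z ≥ 3.2 and TH Z ≥ 1.2) or (TH Z ≥ 3.2 and L1 Z ≥ 1.2)`.
- Radiographic hip OA: Croft ≥ 3 (primary) or ≥ 2 (sensitivity); incident
  OA: baseline Croft < 3 and follow-up ≥ 3; progression: any Croft
  increase with baseline ≥ 3.
- Models: 1 = unadjusted; 2 = age + sex; 3 = + weight, height, activity
  (+ HBM when a cam exposure is tested against an OA phenotype).
  Sex-stratified analyses drop sex and use age, weight, height, activity
  as the adjusted model. References: sex = female, activity = 0–1 h/week.
- Complete-case handling throughout, with excluded counts logged; models
  that fail are reported as unconverged rows, never dropped silently.

## Problem sizes

The validation grid uses cam onsets 40–110° in 5° steps; the simulation
study uses 200 replicate cohorts of 1000 individuals (2000 hips), enough to
resolve a ±3% coverage band with ~1.5% binomial Monte-Carlo sd while the
full test suite stays interactive (<1 minute).

## Known limitations

- The generators certify internal consistency, not external validity; no
  pixel-level image synthesis, DXA screening or BMD measurement error is
  modelled, and follow-up attrition is non-informative by construction.
- The GEE module offers only independence/exchangeable structures and
  binary outcomes; no conditional (mixed-effects) models, Firth correction
  or Bayesian estimation.
- The published adjusted (Model 2/3) and longitudinal odds ratios depend on
  individual-level data that the printed tables do not determine, so they
  are covered here by the oracle-equivalence and simulation-recovery
  properties rather than by direct reproduction; the unadjusted estimates
  and prevalences are reproduced exactly from the printed counts.
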