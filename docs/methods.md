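# Methods

## The task and the data model

A two-flash time-reproduction trial is described by a subject label, a
sample interval *t*ₛ (0.8 or 1.2 s), a horizontal flash separation *l*
(degrees of visual angle; 1.414°·i, i = 0..16 in the separation
experiment), a signed flash location (±12° or 0°, used only in the
same-location control), and a production time *t*ₚ > 0.  Trial tables are
pandas DataFrames with one row per trial; the CSV schema is
`subject_id, experiment, sample_interval_s, distance_deg, location_deg,
trial_index, production_time_s`.  All angles are degrees and all times
seconds throughout the API and the files.

## Observer models

**Constant-speed observer.**  The percept is
*t*ₑ = ω·*t*ₛ + (1 − ω)·*l*/*v*₀ with a weight ω per sample-interval
condition, a shared prior speed *v*₀ (deg/s), and a shared Weber fraction
*w*ₚ.  The same expression arises as the posterior mean of a Gaussian
measurement (SD σ_m) combined with a Gaussian prior over the elapsed
interval centred on *l*/*v*₀ (SD σ_τ), with ω = σ_τ²/(σ_τ² + σ_m²); σ_m
and σ_τ are not separately identifiable from reproduction data and enter
only through ω.  `posterior_mean` exposes the derivation form and is
tested against dense-grid quadrature of the Gaussian product.

**Slowness observer.**  Speed has a zero-centred Gaussian prior (SD σ_v);
temporal and spatial measurements carry Gaussian noise (SDs σ_t per
condition, σ_s per separation).  The reduced estimator is the root
*t*ₑ ≥ *t*ₛ of

    t_s = t_e · (1 − 2·[ l·(σ_t/σ_s)·(σ_v/σ_s) / (((σ_v/σ_s)·t_e)² + 2) ]²)

This grouping is the only one consistent with the three limits the model
must satisfy: no illusion at *l* = 0, at σ_t → 0 (perfect temporal
information) and at σ_v → ∞ (uninformative speed prior).  The equation is
even in σ_t and σ_v (both appear squared or inside a squared bracket), a
property the unconstrained six-parameter fit exploits: sign flips leave the
likelihood unchanged, so negative fitted σ's are reported and flagged
rather than breaking the solver.

**Spatial noise.**  Acuity thresholds (JNDs, arcmin) grow with retinal
eccentricity as 0.93·ε^0.69 (Vernier) or 1.34·ε^0.71 (grating).  Dividing
by 60 (arcmin → degrees) and by 0.6475 (JND → Gaussian SD for the 25–75%
psychometric points) gives σ_s = 0.0239·ε^0.69 resp. 0.0345·ε^0.71
degrees.  Eccentricity of either flash is taken as the radial distance
√((l/2)² + 2.865²): the flashes sit 2.865° above fixation, symmetric about
the vertical meridian, so both share one eccentricity and σ_s is evaluated
once per separation.  This choice keeps σ_s > 0 at l = 0; a
horizontal-only convention (ε = l/2) is available as a switch
(`flash_eccentricity(..., mode="horizontal")`) for sensitivity analyses.

**Production stage.**  Given *t*ₑ, production is Gaussian with mean *t*ₑ
(plus a response bias where applicable) and SD *w*ₚ·*t*ₑ — scalar
variability.  The SD rides on *t*ₑ, not on the bias-shifted mean, because
timing noise is a property of the internal estimate.

## Root solving

The slowness equation is solved per unique separation with a bracketing
scheme: the right-hand side never exceeds *t*ₑ, so f(*t*ₛ) ≤ 0; the upper
edge starts at 10·*t*ₛ and doubles (≤ 60 times) until the sign changes,
followed by 64 bisection steps (bracket width ≪ 1e−12 s).  Every root is
verified by back-substitution with tolerance 1e−9 s; failure raises an
error carrying the inputs.  Uniqueness of the root above *t*ₛ is asserted
numerically over the tested parameter ranges, not proven.  *l* = 0 returns
*t*ₛ exactly without solving, which also avoids the 0·∞ indeterminacy when
σ_s(0) = 0 under the horizontal eccentricity convention.

## Synthetic data

The generator's defaults are the study conditions: 9 subjects, intervals
{0.8, 1.2} s, separations 1.414°·i (i = 0..16), 40 trials per cell (1360
trials per subject), control design {−12°, 0°, +12°} × 40 (240 trials).
Separations are presented in randomised blocks — one shuffled pass through
all levels per block — so cell counts are exact while order is random.
Per-subject parameter sets default to the published per-subject fits
(`population_spec_from_tables`), and a response bias per condition can be
injected.  Non-positive production draws are resampled rather than
clipped; at realistic parameters the truncated mass is < 1e−6, so the
fitted likelihood ignores truncation.  By default the generative estimate
is deterministic given *t*ₛ, matching the fitted likelihood; an optional
measurement-noise mode samples t_m ~ N(t_s, σ_m) first, for
model-mismatch experiments only.

What the generator does **not** emulate: sequential effects (drift,
fatigue, block order), subject-specific spatial acuity, lapses, and
location-dependent biases.  Passing tests therefore show that the pipeline
recovers what it assumes, not that real data satisfy those assumptions.

## Fitting

Both models are fit per subject, jointly over the two conditions (shared
*v*₀ or σ_v and *w*ₚ).  The likelihood is the product over trials of the
scalar-variability Gaussian at the model's deterministic estimate.
Optimisation is Nelder–Mead on transformed parameters — logit(ω), log for
*v*₀, σ_t, σ_v, *w*ₚ — with `xatol = fatol = 1e−10`, 5000 iterations and
10 000 evaluations per restart, and 10 multi-starts by default (tests and
the acceptance study use 2–5; convergence there is dominated by the
moment-based first start).  Initial guesses: ω from the per-condition
intercept of *t*ₚ on *l*, *v*₀ from the slope, *w*ₚ from the pooled cell
CV; σ_v restarts are drawn log-uniform over [0.05, 3] deg/s because the
fitted population spans that range bimodally.  Parameter regions implying
non-positive estimates return a 1e10 penalty so the simplex can recover.

The standard route estimates the response bias first — mean baseline
(zero-separation) production minus *t*ₛ, per subject and condition —
subtracts it, and fits four parameters to corrected data.  The alternative
six-parameter route fits uncorrected data with the biases as free
parameters and leaves ω (classical) resp. σ_t, σ_v (slowness)
unconstrained; boundary or sign pathologies are flagged as degenerate, not
rejected.

AIC is reported per condition as 2k − 2·log L_condition with k the full
parameter count (4, or 6 for the bias variants) attributed to both
conditions; since competing models carry equal k, the between-model Δ is
unaffected by this attribution.  Comparison statistics are the exact
two-sided binomial sign test on paired AICs (ties dropped), and one-sample
or paired t statistics with Cohen's d.

## Identifiability

Two structural flat directions matter and are deliberately documented
rather than hidden:

* **ω–v₀ ridge (classical).**  The data constrain the per-condition
  intercept ω·*t*ₛ and slope (1 − ω)/*v*₀.  At realistic parameters
  (1 − ω ≈ 0.001, *w*ₚ ≈ 0.18) the intercept's sampling SE (~0.011 s at
  680 trials) is an order of magnitude larger than (1 − ω)·*t*ₛ, so the
  likelihood is nearly flat along the ridge that trades ω against *v*₀ at
  fixed slope: profile likelihood varies by < 0.5 nats across a 30-fold
  range of *v*₀.  Bias correction pins the baseline mean at exactly *t*ₛ,
  which pushes the constrained MLE to the ω → 1 (hence *v*₀ → 0) boundary
  in roughly half of simulated replicates.  Consequently *w*ₚ and the
  Kappa slope are recovered precisely, while *v*₀ in isolation is not an
  estimable quantity at this design; tests treat it accordingly.
* **σ_t–σ_v ridge (slowness).**  At the fitted noise magnitudes
  (σ_v/σ_s·*t*ₑ)² ≫ 2, so the estimator depends on the parameters mainly
  through σ_t/σ_v; the individual SDs are set by the weak curvature that
  the "+2" term contributes at small separations.  This is consistent with
  the wide, bimodal spread of fitted σ_v across the published subjects.

## Problem sizes

The default test suite simulates reduced designs (5–9 separations, 10–20
trials per cell) for unit-level checks and the full 1360-trial design for
the recovery study, which uses 20 seeded replicates per generating model
with 2–3 optimizer restarts; the acceptance script mirrors those sizes.

## Known limitations

Only the reduced slowness estimator is implemented, not the full 2-D
space–time posterior; three-flash designs and the Tau effect are out of
scope.  The repeated-measures ANOVA of the location-control experiment is
not reproduced (descriptive means and SEs only).  Spatial variance is
fixed across subjects by the acuity law; the constant 0.6475 JND→SD
conversion assumes the 25–75% JND convention.
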