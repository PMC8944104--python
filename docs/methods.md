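# Methods

## The model

A participant's diurnal activity is treated as a periodic function on
[0, 24) hours, observed as 288 five-minute epoch means averaged over
recording days.  The analysis model is a functional PCA in an orthonormal
Fourier basis:

    y_i(t) ≈ μ(t) + Σ_m s_im φ_m(t),

where the eigenfunctions φ_m are orthonormal under the L2 inner product
⟨f, g⟩ = ∫₀²⁴ f g dt (288-point quadrature, Δt = 1/12 h), λ_m = Var(s_im)
are the component variances, and variance-explained fractions are
λ_m / trace of the coefficient covariance.  Because the basis is orthonormal,
eigenanalysis of the K×K Fourier-coefficient covariance is exactly the
functional eigenproblem; no separate quadrature machinery is needed.

Smoothing is plain least squares (no roughness penalty): each complete
288-epoch profile is projected onto K = 2J + 1 basis functions.  The default
J = 9 resolves features down to about 2.7 h while averaging away epoch-level
noise; it is configurable, and variance fractions shift by fractions of a
percentage point over reasonable J (the quantities are dominated by the
leading smooth modes).

Eigenfunction signs are fixed by a purely algebraic convention — the
coefficient of largest absolute value is made positive — so results are
deterministic but the *scientific* orientation (e.g. whether a positive
amplitude score means more or less activity) is not guaranteed;
interpretation is done by comparing against reference shapes (as the
acceptance script does when it aligns the first component with the
generator's amplitude curve before forming quintiles).

## Preprocessing decisions

- Minutes flagged non-wear or invalid, and missing activity values, never
  enter an average; sleep wear is a valid measurement state.
- Averaging is two-stage: first the within-day 5-minute mean over valid
  minutes, then the unweighted mean over contributing days.  With complete
  data this equals pooling minutes; with partial wear it keeps each day's
  influence equal.
- The epoch grid is anchored at midnight, epoch j = [5j, 5j+5) minutes,
  and curve evaluations use epoch midpoints t_j = (j + 0.5)/12 h.
- Exclusion cascade, in order: age below the floor (25 y); missing
  education, income, work status; no actigraphy; any missing epoch in the
  analysis stratum (both strata for weekday/weekend analyses).  Counts are
  sequential and mutually exclusive and always sum to input − retained.
  No minimum-day rule is imposed beyond epoch completeness.

## Weighted analyses

Survey weights (half the two-year exam weight when two cycles are pooled)
are treated as analytic weights: WLS/weighted-ML point estimates with HC0
sandwich standard errors and normal-quantile (1.96) confidence intervals.
Rescaling all weights by a constant changes nothing; equal weights reduce
exactly to the unweighted estimators.  Design strata and PSUs are out of
scope.  The fPCA itself is unweighted by default with a weighted option,
since weighting is unambiguous only for the regression stage; both modes
are first-class.

Quintile cutpoints are unweighted sample quintiles with ties broken by
stable participant-id order (group sizes differ by at most one).  The trend
test refits the logistic model with the quintile index 1..5 as a single
ordinal term and reports its robust Wald p-value — a standard
epidemiological construction chosen here as the package's own definition.
A quintile whose outcome is constant is reported as a separation diagnostic
rather than an unidentifiable estimate.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
all defaults being this package's own choices (no published generative model
exists for these data):

- **Mean curve** m(t) = night + (day − night)·σ((t−r)/s)·σ((d−t)/s), logistic
  σ; defaults: night 2, day 12 MIMS/min, rise 7 h, decline 21.5 h,
  steepness 1 h — a smooth unimodal adult profile.
- **Components**: amplitude (centered m), early rise (−dm/dt), window
  (sensitivity of m to symmetric widening of the active period), biphasic
  (negative mid-day Gaussian, 13.5 h ± 2 h, restricted to the active
  period), Gram–Schmidt-orthonormalized in that fixed order.  By default the
  shapes are band-limited to the analysis Fourier span (J = 9) so the
  smoother can represent them exactly; raw shapes are available.
- **Scores**: per component, weekday/weekend pairs are bivariate normal with
  variances λ = (4, 2, 1, 0.5), correlations ρ = (0.72, 0.65, 0.5, 0.14),
  and covariate-driven mean shifts (e.g. lower amplitude and earlier rise at
  older ages, shifts for gender, education, work status).  The overall score
  is the day-count-weighted mix (5·weekday + 2·weekend)/7.  ρ₃ = 0.5 is a
  "moderate" placeholder; the first, second and fourth values mirror
  commonly reported weekday–weekend stability of amplitude/timing traits
  versus the schedule-driven biphasic shape.
- **Noise**: per-epoch Gaussian noise (sd 0.5) and a per-day level offset.
  Day offsets act in the constant-curve direction, whose variance after
  averaging the two weekend days is 24·sd²/2; keeping the four components
  identifiable requires this to stay below λ₄ = 0.5, giving sd < 0.14 — the
  default is 0.1.  This is a deliberate structure-over-realism choice: real
  day-to-day variation is larger, so passing recovery tests demonstrates
  correctness of the machinery, not robustness to arbitrary day effects.
- **Clipping**: activity is floored at zero by default (MIMS is
  nonnegative).  Clipping is a nonlinearity the linear fPCA model cannot
  undo, so exact-recovery oracles disable it.
- **Missingness**: geometric non-wear blocks (mean 60 min) flagged until a
  target minute fraction is reached, plus an optional fraction of
  participants with no usable actigraphy at all.
- **Weights**: log-normal (sd 0.5 on the log scale), normalized to mean 1,
  independent of everything by default; an informative mode ties weights to
  age so weighted and unweighted estimands separate.
- **Health**: P(poor/fair) = logistic(α + Σ θ_k s*_k) on standardized
  overall scores; defaults α = logit(0.15), θ = (−0.5, 0, 0.25, −0.2) —
  lower amplitude and a less biphasic pattern raise the odds of poor/fair
  health, a shorter activity window lowers them, rise timing is null.

### Exact-recovery mode

PCA eigenvectors follow the *sample* score covariance, which for plainly
sampled scores differs from its target by O(1/√n); at n = 500 this rotates
recovered eigenfunctions by enough to cap cosines near 0.996–0.998 however
correct the implementation.  For oracle tests that must distinguish
implementation error from sampling noise, `exact_score_moments` whitens and
re-colors the sampled scores so their sample mean and covariance match the
targets *exactly* (a standard fixed-moments simulation device), and
`GeneratorConfig.exact_recovery()` combines it with zero noise, no clipping,
no covariate shifts and ρ = 1.  Under that configuration the full pipeline
returns the generator's components to machine precision; any regression in
the basis, averaging, fitting or eigenanalysis code breaks it immediately.

## What the tests do and do not show

The generator produces data satisfying the analysis model by construction:
additive components on the activity scale, Gaussian noise, wear states
independent of activity level.  Passing recovery and calibration tests
therefore validates the pipeline's mathematics and bookkeeping — not the
adequacy of the fPCA model for real accelerometry, where missingness can be
informative, day effects are large and structured, and activity is heavily
skewed.  Problem sizes in the test suite and acceptance script (cohorts of
60–600 participants, 200–500 calibration replicates) were chosen as the
smallest sizes at which the checked properties are statistically sharp.

## Known limitations

- No design-based (strata/PSU) variance estimation; weights only.
- No penalized or spline smoothing; the Fourier basis is the only option.
- No imputation: participants with incomplete profiles are excluded, not
  recovered.
- The quintile trend test and CI constructions are conventional choices;
  other defensible definitions exist.
- Minute records are treated as epoch-constant by the generator; real
  within-epoch variation is not emulated.
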