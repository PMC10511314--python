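# Methods

## The model

Daily time use is a 4-part composition x = (sleep, SED, LPA, MVPA) on the
simplex: only relative information is meaningful, and the natural
arithmetic is Aitchison geometry — perturbation x ⊕ y = C(x·y) (C is
closure to sum 1), the centered log-ratio clr(x) = ln x − mean(ln x), and
orthonormal ilr coordinates.  We use *pivot coordinates*: for a chosen
behavior placed first in the order (x₍₁₎, …, x₍₄₎),

z_k = sqrt((4−k)/(4−k+1)) · ln( x₍ₖ₎ / gmean(x₍ₖ₊₁₎…x₍₄₎) ),  k = 1, 2, 3,

so the first coordinate contrasts the pivot behavior against the geometric
mean of the remaining three.  Four such bases (one per behavior) are
built; the non-pivot behaviors keep canonical relative order inside each
basis.  That ordering choice is irrelevant to every reported quantity:
all four bases span the same clr subspace, so the fitted model, its R²,
fitted values and the first coordinate's coefficient are unchanged under
any permutation of the trailing parts (tested).

The change-on-change regression treats the one-year outcome change as
linear in the ilr-expressed compositional change:

Δy_i = β₀ + γᵀΔz_i + δᵀz_i^pre + λ·y_i^pre + covariates + ε_i

with Δz_i = z(post_i) − z(pre_i) (identically, the pivot coordinates of
the perturbation difference post ⊖ pre), baseline composition and
baseline outcome as covariates, plus age, sex and occupational status,
and optionally pre-wave measurement season and follow-up time in days.
The model is refitted once per pivot basis; only the first Δ-coordinate
is reported from each fit.  Because the bases are orthogonal rotations of
one another, the four fits share fitted values, residuals, R² and all
non-compositional coefficients; the four first-pivot betas satisfy
Σ βⱼ = 0 and map to a basis-free clr effect vector aⱼ = (√3/2)·βⱼ (the
factor is sqrt((D−1)/D) with D = 4).

Estimation is ordinary least squares via statsmodels (QR-based, classical
homoskedastic covariance, t-based two-sided 95% CIs and p-values).  No
robust or clustered errors and no multiple-testing adjustment are applied.
Rank deficiency is detected via the QR diagonal before fitting and raises
an error naming the collinear columns.

## Isotemporal substitution

Reallocations move t minutes from one behavior to another at a reference
composition (default: the cohort's pre-retirement compositional mean —
the closure of the part-wise geometric means), leaving the other two
parts untouched and the 1440-min total intact.  The predicted outcome
change is

Δŷ(t) = γᵀ[z(x_realloc) − z(x_ref)] = aᵀ[clr(x_realloc) − clr(x_ref)],

so intercept, baseline and covariate terms cancel and the curve passes
through 0 at t = 0.  The prediction is invariant to which pivot basis was
fitted (tested to 1e-8).  When only published first-pivot betas are
available, the same formula is applied with a = (√3/2)·betas and no CI
(the coefficient covariance behind a published table is not recoverable);
rounded published betas may sum slightly off zero, which perturbs the
prediction at well below reporting precision.

CIs for model-based predictions use the delta method on the Δ-coefficient
covariance block only: var(Δŷ) = ΔzᵀΣ_γΔz with a t quantile at the
residual degrees of freedom.  Covariance with the baseline-composition
terms is deliberately excluded — the prediction is a pure contrast in Δz,
so those terms do not enter its variance under the model.

Reallocation grids are signed (−cap … +cap, default 10-min steps; +t
moves time from the donor to the recipient, −t the reverse) and capped at
±60 min for pairs involving MVPA and ±120 min otherwise, matching the
observed ranges of behavior change the analysis was designed around.
Grid points that would drive the donor behavior to zero or below are
skipped.  Note that reallocations are *not* antisymmetric in log-ratio
geometry: removing 60 min from a 77-min MVPA budget is a much larger
compositional move than adding 60 min, which is why MVPA losses cost more
than equal MVPA gains return.

## Cohort rules

- A measurement day is valid with ≥ 10 h of waking wear time (boundary
  inclusive); a participant enters the analysis only with ≥ 3 valid days
  in both waves.  Behavior minutes are averaged arithmetically across
  valid days and then closed (a compositional-mean alternative is
  available behind a flag).
- Outcome change groups: |Δ| < 0.5 kg/m² (BMI) or < 3.0 cm (WC) is "no
  change"; ties at the cutpoint go to decrease/increase.  Labels are
  assigned per outcome, one BMI label and one WC label per participant.
- BMI categories use half-open bins [25, 30) and [30, ∞), with
  underweight (< 18.5) tallied inside the normal-weight row.
- Zero behavior durations are a hard error (the pipeline assumes strictly
  positive compositions); an optional multiplicative replacement exists
  for synthetic edge studies only and is disabled by default.
- Model-spec exclusions are complete-case: rows missing a field the
  requested specification needs (season, follow-up, self-reported sleep)
  are dropped with a logged count.  Long-sleeper exclusion drops
  self-reported pre-wave sleep strictly greater than 9 h/night.
- Covariate codings: sex woman = 1, occupation manual = 1, season dummies
  with winter as reference; age is age at the pre wave.

## Synthetic cohort

The generator draws logistic-normal compositions — Gaussian pivot
coordinates (sleep-first basis) around the pivot coordinates of the
target centers — which guarantees strictly positive minutes.  Baseline
and change draws are independent by default (clearest for calibration
tests); an optional `baseline_change_corr` couples them, since real
behavior change plausibly depends on baseline.  Outcome changes follow
exactly the linear model the analysis fits, with a known zero-sum clr
effect vector, so end-to-end parameter recovery is checkable; the
intercept is solved so the mean outcome change at the design center
equals a target drift.

Defaults (the study conditions the package emulates): n = 213; centers
(497, 584, 282, 77) and (520, 572, 272, 76) min; pivot-coordinate SDs
0.20/0.25/0.35 (baseline) and 0.10/0.12/0.20 (change); BMI 26.3 (SD 4.8)
kg/m² with drift −0.1; WC 91.4 (SD 13.0) cm with drift −0.9; residual SD
1.0 kg/m² (BMI) and 4.0 cm (WC); age 63.5 (SD 1.1); 82% women, 31%
manual workers, 12% long sleepers, uniform seasons, follow-up ≈ 365 (SD
21) days.  The default clr effects are (√3/2) times the published
first-pivot contrasts for each outcome; the BMI column's rounded values
sum to −0.01, so they are mean-centered before scaling to satisfy the
zero-sum constraint exactly.  The WC channel's residual SD and drift are
the package's own choices (the WC error scale is not published); they
were set once to give WC fits a realistic signal-to-noise ratio relative
to the BMI channel.

Daily wear records jitter each wave composition in pivot-coordinate space
(SD 0.10 by default) and draw waking wear hours around 15.5 h, with a
configurable fraction of days forced below the 10-h validity cutoff.

What the generator does *not* emulate: accelerometer measurement error
and device non-wear structure, seasonal effects on behavior (season is
drawn but has no effect by default), informative missingness, and any
dependence of outcome noise on covariates.  Passing recovery and coverage
tests therefore demonstrates correctness of the estimation machinery
under the assumed sampling model, not robustness to real-data violations
of it.

## Numerical choices and verification sizes

- Simplex sums are enforced to 1e-12 (proportions) and 1e-9 (minutes);
  geometry round-trip tests run at 1e-10 over 1000 random compositions.
- Pivot-basis contrast matrices are orthonormal to 1e-12 with zero-sum
  columns; fit invariance across bases is asserted at 1e-8.
- Calibration: with n = 5000 and residual SD 0.5, the recovered clr
  effect lies within ±0.1 of truth (single seeded cohort) and nominal 95%
  CIs cover the true first-pivot coefficients in ≥ 93% of 200 seeded
  replicates; noise-free cohorts reproduce the generating effect to 1e-6.
  These sizes keep the whole calibration under a minute while leaving
  Monte-Carlo error well inside the asserted margins.
- Ternary projection: part 1 at (0,0), part 2 at (1,0), part 3 at
  (0.5, √3/2); barycentric reconstruction from (x, y) is exact to 1e-12.

## Known limitations

- Two waves only; no mixed/longitudinal models, no >2-part simultaneous
  reallocations, no population standardization beyond the mean reference.
- Classical OLS inference: CIs ignore heteroskedasticity and any
  within-participant measurement-error structure.
- The substitution CI omits covariance with baseline-composition terms by
  construction (see above); if the fitted model were misspecified this
  block could contribute.
- The pipeline emits plot-ready coordinates and series, not styled
  figures.
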