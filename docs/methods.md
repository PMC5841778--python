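# Methods

## Model

For a measurement `y_it` of subject *i* (cohort *c*) at age `x_it`,
with transformed age `t = ln x` centred at a pivot `t̄` (by default the
mean log age of the fitted records, i.e. the log geometric mean age):

```
y_it = s(u_it) + α_c + α_i + ε_it
u_it = exp(γ0 + γ_c + γ_i) · ((t_it − t̄) − β0 − β_c − β_i)
```

* `s(·)` is a natural cubic regression spline with `df` basis columns
  plus an explicit intercept.  The basis excludes the constant
  function, so the curve's level is carried by the intercept and the
  size effects and never aliases the spline coefficients.
* `(α_i, β_i, γ_i)` are the subject's size/tempo/velocity random
  effects, multivariate normal with mean zero and an unstructured 3×3
  covariance `Ψ`.
* `(α_c, β_c, γ_c)` are fixed offsets for each non-reference cohort
  (zero for the reference cohort).
* `β0, γ0` are *global* tempo/velocity fixed effects.  They exist
  because a spline with fixed knots cannot absorb an affine re-map of
  its own domain: without them the overall timing shift and age-scale
  stretch would leak into the random effects and violate their
  mean-zero constraint.  The overall size level is the intercept.
* `ε_it ~ N(0, σ²_c)` independent, with per-cohort variances when
  `per_cohort_residual` is on.

Sign convention: positive `γ` compresses the age axis — the subject
(or cohort) traverses the curve *faster*; positive `β` shifts the
pattern *later*.  Under the log transform, tempo quantities convert to
years by multiplying by the geometric mean age, and `100 γ` reads as a
percentage difference in developmental speed.  Centring the transformed
age makes the velocity stretch pivot at the geometric mean age, which
is what makes those two conversions exact to first order, and — less
obviously — is what makes tempo and velocity statistically separable:
uncentred, `u·s'(u)` (the velocity direction) is nearly collinear with
`s'(u)` (the tempo direction) over any positive log-age range.

## Estimation

Approximate maximum likelihood (ML, not REML) in the Lindstrom–Bates
style, alternating two complete sub-solves:

1. **PNLS step.**  At fixed variance components, the penalized
   least-squares objective
   `Σ ‖y − f‖²/σ²_c + Σ_i u_iᵀΨ⁻¹u_i`
   is minimized over the intercept, spline coefficients, global shifts
   and all subject triples: a vectorized per-subject Gauss–Newton with
   persistent per-subject Levenberg damping (rejected steps re-evaluate
   only the affected subjects' records), alternating with a damped GLS
   step for the linear/global fixed effects, whose direction is exactly
   the joint Gauss–Newton step with the random effects profiled out.
2. **Recentring.**  Per-cohort means of the random effects are
   transferred into the cohort offsets, and the pooled means into the
   intercept and global shifts.  These transfers are exactly
   likelihood-invariant (all terms enter additively) and remove the
   ridge between cohort offsets and cohort-mean random effects that
   would otherwise inflate the estimated covariance.
3. **LME step.**  On the Lindstrom–Bates pseudo-data (linearization at
   the current estimates), the linear mixed model is solved to
   convergence: a short EM warm-up followed by direct L-BFGS
   maximization of the profiled likelihood over a Cholesky
   parametrization of `Ψ` and log residual variances, with analytic
   gradients.  EM alone is far too slow when `Ψ` is nearly singular
   (the size–velocity correlation in weight data exceeds 0.9).
4. **Offset polish.**  The penalized least-squares view of step 1 omits
   the determinant term of the Laplace likelihood, which biases the
   cohort offsets toward zero when one cohort's subjects carry few
   observations.  A few damped Newton steps directly on the Laplace
   objective (finite-difference gradient over the offset block,
   Schur-complement Hessian, profile re-solved at each accepted step)
   remove most of that bias.

The iteration stops when the Laplace-approximate marginal
log-likelihood is stationary to `tol` (relative, default 1e-6); with
cohort contrasts in the model the alternation hands over to the polish
once per-iteration gains fall below 1e-4 relative, since the contrasts'
final refinement belongs to the Laplace objective.  The reported
log-likelihood is the Laplace/FOCE value (Gauss–Newton Hessian) at the
final parameters; `marginal_loglik` recomputes it for arbitrary records
and parameters, and matches brute-force quadrature on toy problems in
the near-linear regime.

Standard errors for the cohort contrasts are Wald, from the inverse GLS
information of the final linearization; in simulation they match the
empirical sampling SD of the estimates closely.

Initialization is deterministic: spline from pooled OLS, residual
variance from the OLS residuals, random-effect covariance diagonal at
10% of the outcome variance for size and 0.01 for tempo/velocity,
offsets and random effects zero.

### Numerical choices

* Spline basis: cubic B-splines constrained to the natural conditions
  (zero second derivative at the boundary knots) with the constant
  direction removed; evaluation beyond the boundary knots is the exact
  linear extension.  Interior knots at equally spaced quantiles of the
  pooled transformed ages; boundary knots at min/max.  An explicit knot
  set can be supplied (`SitarConfig.spline_spec`).
* The per-subject conditional covariance is computed in the
  singularity-safe Woodbury form `(I + ΨZ'WZ)⁻¹Ψ`, falling back to the
  precision form with an eigenvalue-floored `Ψ⁻¹` under extreme
  weights (noise-free data drive `σ²` to its 1e-12 floor).
* Velocity exponents are clipped at ±40 to keep rejected trial steps
  finite.
* Degenerate subjects (fewer observations than active random effects)
  are retained and simply shrink strongly toward zero; the model errors
  only if *no* subject identifies the requested effects.

## Synthetic cohorts

`simulate_cohorts` reads the model forwards: template curve, plus
cohort offsets, plus multivariate-normal random effects, plus Gaussian
noise, with uniform timing jitter (±0.25 y) around each nominal
measurement occasion (none for occasions whose recorded age was
imputed).  One RNG stream (PCG64, seeded) consumed in a documented
order makes every dataset bit-reproducible.

The packaged templates are natural cubic interpolating splines on
log-age through fixed knot tables (documented constants): monotone
height and weight curves for a male-pattern trajectory with a single
pubertal velocity peak near 13.7 y (height ≈ 8.4 cm/y, weight ≈ 6.4
kg/y at peak).  Natural-spline templates — rather than shape-preserving
interpolants — were chosen so the template lies exactly in the fitted
model family when the regression spline is given the template's knots,
which is what makes the noise-free exact-fit check meaningful; the
monotonicity and single-peak properties are verified by test on a
0.01-y grid.  The generator stretches the log-age axis about a fixed
pivot of 9 y (close to the geometric mean age of both default
schedules).

Default scenario (the study conditions the package emulates):

| quantity | sparse cohort | dense cohort |
|---|---|---|
| schedule (y) | 2, 4, 6, 7, 11, 15, 20, 26 | 5–13 annual, 15, 17 |
| n (default) | 300 | 600 |
| residual SD height | 2.5 cm | 2.5/1.6 cm |
| residual SD weight | 2.6 kg | 2.6/1.1 kg |
| offsets (height) | reference | +2.3 cm, −0.048 log-age, +6.8% |
| offsets (weight) | reference | +3.4 kg, −0.030 log-age, +28% |

Random-effect SDs: height 5.7 cm / 0.055 / 0.09, weight 4.2 kg / 0.085
/ 0.26; size–velocity correlation 0.76 (height) and 0.9 (weight),
tempo weakly correlated (0.1) with both.  The sparse cohort's age-2 and
age-20 sweeps are flagged `imputed_age` (no timing jitter) and the two
adult sweeps `reported`, for provenance only.

Outcomes are generated as a linear combination of the six *true*
random effects plus sex effect and Gaussian noise on the log scale;
follow-up log height/weight as size-correlated covariates; the
puberty-timing score as `ρ·standardized true tempo + √(1−ρ²)·noise`
(default ρ = 0.55).

What the generator does **not** emulate: measurement-age recording
errors behind the imputed-age sweeps, informative dropout, real
heteroscedasticity across age, and (by default) violations of the
shared-shape assumption — an optional mis-specification mode adds a
late-pubertal bump to non-reference cohorts to mimic systematically
different weight curves.  Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes; they do not certify
robustness to the ways real cohort data break those assumptions.

## Design notes and limitations

* **Joint-fitting benefit is trait-dependent.**  With the height
  defaults the sole sparse-cohort fit already sits at the information
  ceiling: its tempo predictions correlate with the truth within ~0.01
  of the oracle that knows the true curve and variances, so joint
  fitting cannot improve it.  The benefit materializes for weight,
  where the large, strongly correlated size/velocity effects confound
  the sole fit and the dense cohort's information separates tempo from
  them.  The sole-vs-joint comparisons in the tests and the acceptance
  script therefore use the weight scenario.
* **Cohort-offset bias under design asymmetry.**  With one sparsely
  and one densely measured cohort, the conditional-mode (FOCE-type)
  estimator leaves a small systematic attenuation in the offsets
  (tempo of order 0.01 log-age at n = 150+300) even after the Laplace
  polish, because the profiled Laplace likelihood is nearly flat across
  that region; with symmetric schedules the same estimator is
  unbiased.  Reported SEs remain calibrated.  Tempo offsets between a
  sparse and a dense cohort should be read as slightly conservative.
* Duplicate (subject, trait, age) rows all enter the likelihood; no
  de-duplication or down-weighting of self-reported values (the
  `source` flag is provenance only).
* The growth-impact SD uses divisor *n* (population SD); `ddof=1` is
  available.
* No REML, no autocorrelated residuals, no spline random effects; at
  most the three structural random effects.
* Models are fitted separately per trait and sex; the CLI orchestrates
  the four fits.
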