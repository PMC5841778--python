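# sitarpy

Shape-invariant (SITAR) growth-curve modelling for longitudinal
anthropometry, with joint multi-cohort fitting and second-stage tools
for relating growth parameters to later-life outcomes.

## The model

SITAR (Super-Imposition by Translation And Rotation) assumes every
subject follows one common growth curve, individualized by three simple
transformations.  For a measurement `y` of subject *i* (cohort *c*) at
age `x`, with `t = ln x` centred at the geometric mean age:

```
y = s( exp(γ_c + γ_i) · (t − β_c − β_i) ) + α_c + α_i + ε
```

* `s(·)` — a natural cubic regression spline (the shared mean curve);
* `α_i` — **size**: a vertical shift in trait units (cm or kg);
* `β_i` — **tempo**: a horizontal shift on the log-age axis — the
  timing of the growth pattern; multiplied by the geometric mean age it
  reads in years;
* `γ_i` — **velocity**: a stretch of the log-age axis — how fast the
  subject traverses the pattern; ×100 it reads as a percentage;
* `(α_c, β_c, γ_c)` — fixed offsets for non-reference cohorts (secular
  trends in size, timing and speed of growth);
* `ε` — residual error with a cohort-specific SD.

The subject triples are random effects with an unstructured 3×3
covariance; estimation is approximate maximum likelihood
(Lindstrom–Bates: penalized least squares over subjects and fixed
effects, alternating with a full ML solve of the linearized mixed
model, plus a Laplace-objective polish of the cohort offsets).

The motivating use case is a cohort measured too sparsely through
puberty to pin down pubertal timing on its own: fitting it *jointly*
with a densely measured cohort — shared spline, cohort offsets,
per-cohort residual variances — transfers the dense cohort's
information about the curve's shape to the sparse cohort's subjects.
The per-subject tempo (and size/velocity) predictions then feed
log-scale regressions of later-life outcomes such as bone density
analogues, with the **growth impact** statistic `100 × 4 × SD(linear
predictor)` summarizing the outcome contrast between growth patterns
2 SD below and above the mean.

Everything is testable without access restrictions because the package
ships a synthetic two-cohort generator (`sitarpy.simulate`) whose
defaults emulate the sparse-plus-dense design: measurement schedules
≈ {2, 4, 6, 7, 11, 15, 20, 26} y versus annual 5–13 y + 15, 17 y,
random-effect SDs of 5.7 cm / 5.5% / 9% for height (4.2 kg / 8.5% / 26%
for weight), residual SDs 2.5 vs 1.6 cm, and secular-trend offsets of
about +2–4 units size, earlier tempo and faster velocity — with full
truth tables for every subject.

## Worked example

```bash
python examples/fit_two_cohorts.py
```

prints (abridged):

```
simulated 3160 measurements for 320 subjects in 2 cohorts
converged: True after 4 outer iterations, log-likelihood -7632.9

cohort contrast dense91 vs sparse46 (planted truth in brackets):
  size     +1.63 cm  (+2.30)
  tempo    -0.605 y  (-0.446)
  velocity +6.2 %  (+6.8)

random-effect SDs (generating values 5.7 cm / 5.5% / 9%):
  size     5.60 cm
  tempo    5.34 %  = 0.50 y
  velocity 8.13 %
  residual SDs: sparse46: 2.58, dense91: 1.63

mean age at peak height velocity: 13.19 y (template peak near 13.7 y)
```

The contrasts recover the planted secular trend to within about 2 SE
at this modest sample size, the random-effect and residual SDs match
the generating values, and the fitted mean curve peaks near the
template's pubertal spurt.  The other examples cover outlier cleaning
(`clean_outliers.py`: all 15 injected ±8-SD errors flagged, 0.1% false
flags, residual SD restored from 0.98 to 0.80 cm), sole-versus-joint
fitting (`sole_vs_joint.py`: the sparse cohort's weight-tempo
correlation with a puberty-timing score rises from 0.44 to 0.52 when a
dense cohort joins the fit) and the outcome regressions
(`bone_outcome_association.py`: a planted height-tempo effect of −0.65
recovered with t ≈ −4.7 and a ~15% tempo-only growth impact).

A thin CLI wraps the same functions for scripted pipelines:

```bash
sitar simulate --config config.yaml --seed 1 --out-dir out/sim
sitar fit      --config config.yaml --growth out/sim/growth.csv --out-dir out/fits
sitar clean    --config config.yaml --growth out/sim/growth.csv --out-dir out/clean
sitar summarize --fit-summary out/fits/fit_height_joint.json --out-dir out/summ
sitar associate --outcomes out/sim/outcomes.csv \
    --fit-height out/fits/fit_height_joint.json \
    --fit-weight out/fits/fit_weight_joint.json --out-dir out/assoc
sitar compare  --fit-sole out/fits/fit_height_sole_sparse46.json \
    --fit-joint out/fits/fit_height_joint.json --cohort sparse46 --out out/cmp.csv
```

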