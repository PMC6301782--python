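# Methods

## The problem

Growth references tabulate, per sex and age in months (0–240), either the
measurement values at fixed z-levels (−2, −1.5, …, +2) or the three LMS
parameters — Box-Cox power `L`, median `M` (kg, cm or kg/m²), generalized
coefficient of variation `S` — from which any z or centile follows in closed
form. A z-score calculator maps an observation `(sex, age, X)` to `z`;
classification at the fixed cut-offs −3, −2, +2, +3 turns that into
nutritional status. `pedzscore` implements three calculators over the same
tables and the protocol to compare them.

## The three calculators

**WHO first-moments.** `z = (X − m)/SD`. When only a z-score grid is
available, `m` is the value at `z = 0` and `SD` the symmetric half-difference
of the values at ±1: `SD = (X(+1) − X(−1))/2`. This deliberately retains only
first-moment information; on a skewed reference the method is exact at the
median and increasingly wrong toward the tails, which is the phenomenon the
stage-1 comparison measures. (How the reference SDs "should" be obtained is a
genuinely open design point; the grid-derived choice is the one consistent
with using first-order moments only.)

**Cole/CDC-LMS.** `z = ((X/M)^L − 1)/(L·S)` for `L ≠ 0`, `z = ln(X/M)/S` at
`L = 0`; inverse `X(z) = M(1 + LSz)^{1/L}` (`Me^{Sz}` at `L = 0`). The
branch switch happens at `|L| < 1e−7`, where the two formulas agree to ~1e−7
relative — continuity is tested. `1 + LSz ≤ 0` marks the unrepresentable tail
for that `(L, S)` and raises a domain error rather than returning a complex
number. Between tabulated ages, `L`, `M`, `S` are interpolated linearly and
independently; there is no extrapolation beyond the table's span, because
reference tails beyond the tabulated range are not trustworthy. Recovery of
`(L, M, S)` from a grid row is a bounded least-squares fit of the inverse
form (initialized at `L = 1`, `M = X(0)`, `S` from the moments summary),
which recovers generating parameters to better than 1e−6 on 9-level rows.

**Gaussian-process regression.** An exact GP over standardized predictors
`[sex, age, X]` (sex encoded male = 0 / female = 1, then all three shifted
and scaled to zero mean, unit variance by training statistics stored in the
model). Prior mean is fixed at 0: z-scores are centred by construction, and
reversion to `z = 0` is the least surprising behaviour far from data. Four
stationary kernels are implemented (squared exponential, exponential,
Matérn 5/2, rational quadratic), isotropic by default — matching the
unqualified kernel names in common toolboxes — with per-dimension (ARD)
length scales behind a flag. Hyperparameters (signal variance, length
scale(s), noise variance, and the rational-quadratic shape α) maximize the
log marginal likelihood by L-BFGS-B in log-parameter space with analytic
gradients, 5 restarts from seeded perturbations of a data-driven start
(signal variance = target variance, length scale 1 in standardized units,
noise = 1e−4 × target variance). The Cholesky factorization escalates a
diagonal jitter 0 → 1e−8 … 1e−4 before declaring the matrix non-PSD. Fits
are deterministic for a fixed seed.

The GP is the package's own implementation end to end; scipy provides only
the factorization and the optimizer. scikit-learn's GP appears exclusively
as an independent cross-check in the test suite, alongside a naive
direct-inversion predictor written from the textbook equations.

## Synthetic references

`synth_lms_table` builds LMS tables from smooth per-sex age trends and the
LMS closed form, so every downstream computation is testable offline:

* **HFA**: saturating median `50 + 130a/(a+70)` cm (female ×0.985),
  `L = 1` (height treated as unskewed), `S` 0.035→0.045;
* **WFA**: convex median `3.4 + 16a/(a+40) + 0.18a` kg (female ×0.96),
  `L` −0.3→−1.2 (right-skew growing with age), `S` 0.11→0.19;
* **BMIFA**: median dipping to 15.4 kg/m² near age 5 then rising to 21.5 at
  age 20, `L` −1.8→−1.2, `S` 0.08→0.13.

These imitate the broad magnitudes and shapes of published growth charts
without reproducing any real chart. A seeded, age-linear log-scale
perturbation (1% scale) on `M` and `S` makes distinct seeds give distinct
but equally smooth references; `L` follows its trend exactly so structural
properties (e.g. the symmetric `L = 1` height reference) hold for every
seed. The three kinds' trends are internally plausible individually but not
calibrated jointly (a weight median divided by a height median squared does
not reproduce the BMI median), which is irrelevant to the method
comparisons but means absolute synthetic BMI levels should not be read as
realistic.

Training grids for the GP use **log-spaced ages** (dense in infancy, sparse
in adolescence). The reference median changes fastest in the first months of
life; uniform age spacing under-resolves that region and concentrates the
GP's held-out error there, while log spacing mirrors how real references
sample infancy densely.

Consequently, what passing tests show is that the calculators and the
comparison machinery are correct against closed-form and enumeration
oracles on references with realistic shape; they do not certify agreement
with any real CDC/WHO chart, for which the user supplies the actual files
(they load unmodified).

## Cohort simulators

**Screening population (stage 2).** Three age clusters at 35, 45 and 65
months, 3000 records, equal group weights, sex ratio 0.5. "Spread of 10%"
is read as a relative SD: age ~ Normal(μ_g, 0.10 μ_g) and height ~
Normal(M(sex, age), 0.10 M) truncated to [86, 121] cm, tying height to the
reference median at the drawn age so age–height clusters are correlated.
Implausible observations arise naturally in the truncated-normal tails; no
separate injection mechanism exists. One random substream per record
(SeedSequence children) means growing `n_total` never changes earlier
records.

**Longitudinal cohort (stage 3).** 212 children, 731 visits by default
(every child at least one visit; the surplus multinomially allocated). Each
child draws a sex (52.8% male), a baseline age (Normal(116.5, 55) months
truncated to 2–18 years) and persistent height and weight z-scores
(means −0.15/−0.3, SDs 1.1/0.9, correlation 0.7); visits advance age by
1–6 months. Heights follow the child's height z through the reference (so
they are non-decreasing, with an explicit guard), weights add a small
per-visit wobble (SD 0.05 z) to the child's weight z, and BMI is derived as
`weight/height²`, never drawn.

## Comparison protocol

**Stage 1** scores every grid cell `(sex, age, z, X(z))` with all three
methods; residual = tabulated z − calculated z. CDC-LMS scores its own
generating grid to machine precision; WHO does so exactly when `L = 1`; the
GP after convergent training on the grid. Reports carry per-method summary
statistics, all recomputable from the emitted per-record frame.

**Stage 2** compares CDC-LMS and GPR on the simulated population via the
relative error `|z_GPR − z_LMS| / |z_LMS|`, banded at >30% and (10%, 30%].
The denominator is ill-defined near `z = 0` — precisely where the methods
disagree most — so pairs with `|z_LMS| < 0.01` are excluded from the band
fractions and tallied separately rather than silently divided.

**Stage 3** computes per-kind paired differences `z_LMS − z_GPR` with
summaries and a 95% CI of the mean, a Wilcoxon signed-rank test per kind
(zeros dropped — Wilcoxon's original convention; exact null for n ≤ 25,
normal approximation with continuity correction above — via scipy, checked
against full sign-flip enumeration in the tests), a one-way ANOVA across the
three kinds' difference distributions, and a per-observation >5%
relative-error flag (same guard; guarded pairs form a third overlay
category). "Absolute error" in stage 2 is unsigned; stage-3 differences
keep their sign.

## Numerical choices

* LMS log-branch switch at `|L| < 1e−7`; least-squares recovery bounded to
  `L ∈ [−10, 10]`, `M, S > 0`, gradient tolerance 1e−10.
* GP log-parameter bounds: signal variance e^±20, length scale e^±10, noise
  ∈ [1e−10, e^5], α ∈ e^±5; jitter ladder 1e−8 → 1e−4.
* Predictive variance clamped at 0 against round-off; it includes the noise
  term.
* Status cut-offs are half-open, closed below: `[−3, −2)` is moderate, so
  `z = −3` classifies moderate and `z = −2` normal.
* Model persistence is versioned JSON holding kernel, hyperparameters,
  standardization constants, raw training inputs and dual coefficients at
  full precision; loading reuses the stored dual coefficients so
  predictions are bit-identical, and rejects tampered (non-positive)
  hyperparameters or unknown schema versions.
* RMSE is the root of the **mean** squared error throughout. (One common
  variant reads "rooted median squared error"; the mean-based definition is
  the standard regression metric and the one implemented, with `mse`,
  `mae` and `r2` reported alongside.)

## Problem sizes

Default desk-scale configurations, chosen so the full pipeline runs in
minutes on one CPU: GP training grids of 2 sexes × 60 log-spaced ages × 9
z-levels (1080 points) for the headline function-recovery check and 2 × 31 ×
9 (558) for the stage models; 3000-record stage-2 cohorts; 212 children /
731 visits in stage 3; oracle-equivalence problems at 200 points. Exact GP
inference is O(n³), so real CDC tables (~8700 points per measurement) fit in
minutes rather than seconds; no sparse approximation is provided or needed
at these sizes.

## Known limitations

* Synthetic trends are a fixture, not a chart: absolute levels (especially
  BMI) are not jointly calibrated, and conclusions about real references
  require the real files.
* The WHO method's reference moments are grid-derived (see above); other
  published-SD conventions would shift its stage-1 residuals.
* Linear age interpolation of L, M, S introduces curvature-bounded error
  between knots; tables should be supplied at the density the application
  needs.
* The GP assumes a stationary kernel over standardized predictors; strongly
  non-stationary references (infancy vs adolescence) are handled by knot
  density, not by the kernel.
* No weight-for-height references, no modified BMI z-scores for severe
  obesity, and no reconstruction of references from raw survey data.
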