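# Methods

This note documents the statistical model, the estimation machinery, the
synthetic-data generator, and the design choices behind `mediboot`, at the
level of detail a reviewer or maintainer needs to judge what the package's
passing tests do and do not demonstrate.

## Data model

The pipeline's single input container is a long-format table: one row per
(subject, timepoint, variable), with a binary arm code (0 = control,
1 = intervention) and a binary timepoint code (0 = baseline, 1 = follow-up).
Structural invariants are enforced at construction: at most one record per
(subject, timepoint, variable); arm constant within subject; every subject
has baseline records (follow-up may be missing — dropout); variables flagged
for log transform are strictly positive until the transform is applied.
Missing follow-up visits are represented by absent rows, never imputed:
mixed-model estimation uses all available rows and is unbiased under
missingness at random.

Coding conventions fix all coefficient signs: a negative group-by-time
coefficient for a symptom scale (e.g. anxiety) means the intervention arm
improved (declined) more than control. The log transform is the natural
logarithm; T-scores use the standard affine map `50 + 10·(x − μ_ref)/σ_ref`;
the clinically-meaningful-change classifier uses |Δ| ≥ 3 T-score points
(inclusive, direction-agnostic — the threshold convention for these
patient-reported measures).

## Mixed-effects engine

Every path model is a linear mixed model with a subject random intercept
over at most two timepoints:

```
y_it = x_itᵀβ + u_i + ε_it,   u_i ~ N(0, τ²),  ε_it ~ N(0, σ²_t)
```

Two residual structures are supported. `compound_symmetry` (default) uses
one σ² for both timepoints, giving the marginal 2×2 covariance
`[[σ²+τ², τ²], [τ², σ²+τ²]]`. `heteroscedastic_time` allows separate
baseline and follow-up residual variances — the richest structure
identifiable from two timepoints alongside a random intercept. A fully
unstructured 2×2 marginal plus a random intercept is over-parameterized at
two timepoints, which is why the package does not offer it.

**Estimation.** Because each subject contributes either a complete
(baseline, follow-up) pair — whose 2×2 covariance is identical across
subjects and invertible in closed form — or a single row with scalar
variance, the (restricted) likelihood is profiled analytically: given the
variance *ratios* (λ = τ²/σ², and the follow-up/baseline residual ratio in
the heteroscedastic mode), the GLS fixed effects and the residual scale are
closed-form, so the optimizer searches over one ratio (bounded Brent on the
log scale, tolerance 1e-9, range e^±20) or two (Nelder–Mead, 400-iteration
cap). A fit costs well under a millisecond, which is what makes
bootstrap-of-mixed-model and coverage simulations practical on one CPU.
Optimizer failure is surfaced as `converged=False` and never silently
retried with altered data. On noise-free inputs the profiled residual
variance is floored at 1e-30 so the criterion stays finite; point estimates
are exact there by construction. The test suite cross-checks estimates,
standard errors and variance components against an independent
general-purpose implementation (statsmodels `MixedLM`) on unbalanced data.

**Inference.** Fixed effects get Wald-normal (z) tests and 95% CIs. No
small-sample degrees-of-freedom correction (Satterthwaite/Kenward–Roger) is
applied; at n≈87 subjects the difference is modest, but P values near the
0.10 gate can be slightly liberal. REML is the default; full ML is
selectable, and AIC is exposed only under ML where it is comparable across
fixed-effect structures.

On balanced complete data the group-by-time estimate equals the
difference-in-differences of the four cell means exactly, for any variance
components — the engine's primary correctness oracle.

## Mediation and the gate

Paths a and c are group-by-time coefficients from the mediator and outcome
models. Path c′ and path b come from the outcome model that adds the
mediator as a **time-varying covariate** (its concurrent value at each
timepoint); a baseline-adjusted change-score formulation was the main
alternative and is intentionally not the default, since the repeated-measures
model family is applied uniformly to every step. Path b is therefore
*adjusted* for group and time; the unadjusted simple-association variant is
available behind a flag (`adjusted_b=False`) because the verbal definition
("the mediator is associated with the outcome") is ambiguous. Swapping the
mediator and outcome names runs the reverse-direction exploratory analysis
with no special code path.

The gate requires P < α on a, b and c simultaneously, strict inequality,
default α = 0.10 — a deliberately liberal a-priori level for small pilot
trials; P = 0.10 exactly fails. No multiple-testing correction is applied
across (mediator, outcome) pairs; the report instead states the number of
pairs tested. The indirect effect is the difference of coefficients
`c − c′`. In the linear Gaussian model with no exposure–mediator
interaction this coincides with `a·b`; the package computes both routes in
its consistency tests but reports `c − c′`.

## Bootstrap

The resampling unit is the **whole subject** (cluster bootstrap): each drawn
subject carries all its rows, preserving the within-subject correlation the
random intercept encodes. Resampling is stratified by arm, so every
replicate reproduces the per-arm allocation exactly; unstratified resampling
is available behind a flag. Each replicate refits the c and c′ models and
records `c − c′`. The CI is the percentile interval — empirical
(1±level)/2 quantiles with linear interpolation between order statistics;
BCa and parametric bootstraps are out of scope. Significance means zero
strictly outside the interval.

Defaults: 200 replicates (the conventional figure for this design; ≥1999
recommended for production so the bounds fall on order statistics), level
0.95. A replicate whose refit fails to converge is redrawn up to 5 times,
then counted as failed; failures are reported in the result and a warning is
attached above 10%. Randomness policy: one master seed; each
(mediator, outcome) pair derives its own substream by mixing the seed with a
CRC of the pair's names, so adding or removing a pair never perturbs the
others' draws — this is what makes report-level byte-for-byte
reproducibility and pair-removal invariance testable.

## Synthetic trial generator

The generator emulates the structure of a small two-arm exercise RCT:
43 intervention / 44 control subjects, two timepoints, and one
dropout per arm (follow-up visit removed for a uniformly chosen subject per
arm, independent of all values — MCAR by construction, hence MAR as the
models assume). The generative model is the same linear random-intercept
model the engine fits, with the mediator entering the outcome
contemporaneously:

```
M_it = μ_M + δ_M t + a·g·t + u_i + ε_it
Y_it = μ_Y + δ_Y t + d·g·t + b·M_it + v_i + η_it
```

so the implied total effect is `c = d + a·b` and the true indirect effect is
`a·b`. Gaussian errors and no exposure–mediator interaction are deliberate:
that is the minimal model under which the difference-of-coefficients and
product-of-coefficients estimators target the same quantity, which the
consistency tests rely on.

Defaults (chosen once, as plausible values for T-score measures in this
population, and not revisited): baseline means 55.2 (mediator) and 45.4
(outcome); τ² = 40 and σ² = 24 for both variables, i.e. total SD 8 with
intraclass correlation 0.625 over 12 weeks; a = −1.5 T-score points
(the magnitude reported for anxiety in trials of this kind), b = 0.4, no
direct effect; small secular trends (−0.3 mediator, +0.5 outcome) in the
control arm. The outcome's realized variance additionally inherits
`b²·Var(M)`. In `biomarker_mode` the linear model holds on the natural-log
scale and strictly positive log-normal values are emitted; scale parameters
are then interpreted on the log scale and should be overridden (the T-score
defaults are nonsensical there). Extra null variables (no effects, no
cross-links, same covariance structure) can be appended to exercise
multi-pair analyses.

**What the generator does not emulate:** item-level measurement,
floor/ceiling effects and the discreteness of real T-scores, baseline
covariate imbalance, informative dropout, heavier-tailed errors, and any
exposure–mediator interaction. Passing calibration tests therefore show the
procedure is correct *under its own assumptions* at this design size — not
that those assumptions hold in any particular real trial.

## Operating characteristics (what the simulations measure)

* **Indirect-effect consistency** — across 100 replicate trials at 500 per
  arm (a=2, b=0.5, d=0), the mean `c − c′` recovers 1.0 within Monte-Carlo
  error, and `c − c′` agrees with `a·b` per replicate.
* **Coverage** — 100 trials at the 43/44 design with one dropout per arm,
  199 bootstrap replicates each: the percentile CI covers the true `a·b` in
  roughly 92–96 trials; percentile intervals at n≈87 sit slightly below the
  nominal 95%, as expected.
* **Null behavior** — with a = b = 0, trials that both pass the gate and
  produce a zero-excluding CI are rare (0–3 per 100 in practice); the triple
  gate at α = 0.10 is the dominant filter.

Problem sizes (replicate counts, subjects per arm, bootstrap draws) were
chosen so each harness completes in seconds to about a minute on one CPU
while leaving Monte-Carlo error comfortably inside the asserted bands.

## Reporting

Baseline comparisons use Welch's unequal-variance t-test by default (a
pooled-variance option exists) for continuous variables and chi-square
without continuity correction for categorical ones, with a warning — not an
automatic exact test — when expected counts drop below 5, and a note instead
of a test for single-level variables. Reports render deterministically
(input order preserved, numbers at 2 decimals) as text, TSV or JSON; path
significance at the gate level is marked solid/dashed in text mode. Every
model fit is logged (spec, subjects, observations, convergence, runtime) at
INFO level.

## Known limitations

* Wald-normal inference can be liberal near the gate threshold at small n.
* Only two timepoints; no random slopes; no GEE alternative.
* Single mediators only — no multiple-mediator decomposition, no
  sensitivity analysis for sequential ignorability, no exposure–mediator
  interaction decomposition.
* The percentile CI with 200 replicates is noisy; its endpoints interpolate
  deep order statistics.
* The causal interpretation of `c − c′` requires no unmeasured
  mediator–outcome confounding, which randomization of the *arm* alone does
  not guarantee.
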