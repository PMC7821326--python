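# Methods

## Design and data model

A partially nested trial randomizes individuals to a control arm
(treated individually) or to a group-administered intervention.
Clustering arises from treatment delivery, not randomization, so it is
present in one arm only and — under noncompliance — only among the
patients who actually attend a group. Compliance is binary and observed
only in the intervention arm. Two latent classes are assumed:
*compliers* (probability π, i.i.d. Bernoulli in both arms) and
*never-takers*; always-takers and defiers are excluded (monotonicity;
the group treatment is unavailable to controls), and the exclusion
restriction makes the never-taker outcome distribution identical in
both arms.

Outcomes are Gaussian:

* never-taker, either arm: `y = μ + γ + e_N`, `e_N ~ N(0, σ_N²)`;
* complier, control arm: `y = μ + e_C`, `e_C ~ N(0, σ_C²)`;
* complier in a therapy group: `y = μ + τ + u_AG + e_T`,
  `e_T ~ N(0, σ_T²)`, with one shared `u_AG ~ N(0, σ_u²)` per actual
  group.

Parameterization used throughout: ρ = σ_u²/(σ_u² + σ_T²) is the ICC of
treated compliers, λ = (σ_u² + σ_T²)/σ_N² the complier/never-taker
variance ratio, and the generator fixes σ_N² = σ_C² = 1 so that
σ_u² = ρλ and σ_T² = (1 − ρ)λ. The ITT estimand is δ = πτ; the CACE is
τ.

Group identifiers: every intervention subject receives an intended
group `IG(i)` (filled sequentially in randomization order in blocks of
`group_size`; a remainder forms a final smaller group); the actual
group `AG(i)` replaces the label by the subject's own id for
noncompliers, so actual groups are nested in intended groups, a lone
complier stays a cluster of size one, and a fully noncompliant group
disappears as a cluster. Control subjects carry their own id as both
identifiers. The random effect is indexed by the actual group:
noncompliers carry no share of `u`. Simulated datasets retain the
latent class purely for oracle checks; no estimator reads it.

## Estimators

**ITT.** OLS of `y` on the randomization indicator (plus optional
linear covariates) ignores clustering; cluster-robust variants keep the
OLS point estimate and use the sandwich over intended or actual groups
with the small-sample multiplier `[G/(G−1)]·[(n−1)/(n−p)]` and a
t(G−1) interval, counting every unclustered subject as a cluster of
size one (this mirrors the conventions of the major commercial
implementations so that coverage results are comparable; statsmodels'
cluster covariance implements exactly this form). GEE uses an
exchangeable working correlation with moment updates and robust SEs.
The random-effects family is fitted by full Gaussian maximum
likelihood:

* RI(Int)/RI(Act): compound symmetry — every subject carries the group
  intercept, so control singletons contribute total variance
  σ_u² + σ_e² with an unidentified split;
* RE(Int)/RE(Act): the random intercept enters only with `r` (intended)
  or `t` (actual) and the two arms have separate residual variances;
* RE(Act-Het): three residual strata (control, treated compliers,
  intervention-arm never-takers) with the random effect on treated
  compliers; reports λ̂ = (σ̂_e1² + σ̂_u²)/σ̂_e2². With no observed
  never-takers the model is unidentified and falls back to RE(Act) with
  a warning.

ML rather than REML is used everywhere, with Wald z intervals for
ML/GEE fits and t intervals for OLS-based fits — again matching the
reference conventions the coverage figures assume.

**Causal.** Two-stage least squares instruments receipt `t` with
randomization `r` (equal to the Wald ratio without covariates); its
robust variant uses the actual-group cluster sandwich with a `G/(G−1)`
correction and z intervals. The Bloom-type random-effects estimator
fits `y = α + β_t t + β_s s + u_AG t + e` (with `s = (1 − t)r` and the
three residual strata above) and combines
`(π̂β̂_t + (1 − π̂)β̂_s)/π̂` with π̂ the observed intervention-arm
compliance proportion; its SE comes from the delta method on the joint
ML covariance of `(β̂_t, β̂_s)` with π̂ treated as an independent
binomial proportion — its contribution is second order, and the
combination is implemented exactly as written even though finite-sample
`β̂_s ≠ 0` makes it differ from `β̂_t`.

The normal-mixture family maximizes the full-information likelihood in
which the intervention arm contributes, per actual group, a
multivariate normal for its compliers (covariance σ_u²J + σ_⋆²I, where
σ_⋆² is σ_C², or σ_T² under the heteroscedastic option) plus
independent normals for never-takers plus the Bernoulli class terms,
and each control subject contributes a two-component log-mixture
accumulated with `logaddexp`. π, γ and the component variances are
shared across arms, so component membership is anchored by the observed
`t` — label switching is impossible by construction — and π is
estimated jointly from both arms. Standard errors come from the
observed information (inverse numerical Hessian on the unconstrained
scale), from the outer product of unit scores, or — for the robust
variants — from a cluster sandwich whose scores are numerical
derivatives of per-unit log-likelihood contributions (units: actual
groups, noncomplier singletons, control subjects).

**Closed forms.** `bias.py` evaluates the weighted-ITT approximation,
the actual-group bias `(γ−τ)π(1−π)(D−1)/(π+(1−π)D)` and its `λD`
modification, and the apparent (inflated) ICC. The apparent-ICC
expression uses the *squared* mean difference by default — the
inflation of the between-group variance is by the square of the gap
between the complier mean and the arm mean, and only the squared form
is bounded below by ρ as the derivation requires; the first-power
rendering is available as `variant="as_printed"` for comparison. Group
size `m` may be non-integer so that a mean observed group size can be
plugged in.

## Numerical choices

Variance parameters are optimized on the log scale, floored at
`exp(−30)` so that boundary estimates (σ̂_u² = 0 is legitimate, not a
failure) are representable; optimization is Nelder-Mead from
moment-based starting values with jittered restarts on failure. In the
mixture fits, parameters pinned at the log floor are treated as
boundary estimates and inference uses the observed information over the
interior parameters only (the likelihood is flat in the boundary
directions, so the full Hessian is singular there by construction); a
fit is a *failure* only if the optimizer fails after restarts or the
interior Hessian is not positive definite. Failures are caught and
counted per method by the study harness, never propagated.

The marginal Gaussian likelihood is evaluated blockwise with the
Woodbury identity, reducing each evaluation to grouped sums, and β is
profiled out by GLS; the same machinery yields the model-based
fixed-effect covariance `(X'V⁻¹X)⁻¹`. On the balanced simulation grid
(equal intended group sizes) the intended-group RE model has an exact
closed-form ML solution (one-way ANOVA components with boundary
truncation), and cluster-robust OLS reduces to grouped residual sums;
`simstudy.grid_coverage` exploits both, vectorized across replicates,
and the test suite verifies the fast paths against the general fitters
to near machine precision.

Replicate streams are spawned from one master seed per scenario cell
(`numpy.random.SeedSequence`), so results are bit-reproducible and
independent of execution order or worker count.

## Simulation study scale

The evaluation grid is the full 216-cell factorial (γ from −1 to 1 in
steps of 0.25; ρ ∈ {0.05, 0.1}; π ∈ {0.7, 0.8}; m ∈ {5, 10};
λ ∈ {2/3, 1, 3/2}; τ = 0; 200 subjects per arm). The package's own
reproduction runs 500 replicates per cell for the coverage summaries
and 200-replicate single cells for the directional bias and ICC
checks — a desk-scale choice whose Monte-Carlo standard errors
(~0.07 percentage points for a grid-mean coverage, reported alongside
every scenario summary) are small relative to the effects of interest.
Parameter-recovery checks use 5000 subjects per arm.

## What the generator does and does not emulate

It reproduces the latent-class structure exactly: Bernoulli compliance
in both arms, shared never-taker distribution (exclusion restriction),
group random effects for attending compliers only, sequential group
filling, and the intended→actual identifier construction. It does not
emulate always-takers, group switching or multiple membership, missing
outcomes, longitudinal follow-up, binary outcomes, variable intended
group sizes, or covariate-dependent compliance. Passing tests therefore
demonstrate correctness of the estimators under this generating model,
not robustness to those complications; in particular the unbiasedness
of intended-group analyses shown here leans on the absence of
always-takers and of group switching.

## Known limitations

* The closed-form bias expressions are first-order approximations that
  ignore the induced bias of the ICC (and of λ); the simulation harness
  shows the homoscedastic form under-predicts the true bias as |γ − τ|
  grows.
* The random-effects instrumental-variables estimator is deliberately
  not implemented: with a random effect in the instrument model, all
  instrument variation is between clusters and never-takers receive
  extreme weight, making that construction unsuitable for this design.
* Mixture SEs rely on numerical differentiation; in tiny samples the
  observed-information and outer-product variants can differ
  appreciably (both are exposed).
* Reference implementations may use moment/GLS variance estimators for
  the random-intercept model rather than ML, so third-decimal agreement
  with published case-study tables is not guaranteed for those rows.
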