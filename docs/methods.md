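# Methods

This note records the statistical models, the numerical choices, and the
limits of what the synthetic-data tests can show. All notation: g groups
(here 3), n samples (here 45), p variables (fatty acids, % of total FAs).

## Data model and units

A fatty-acid profile maps canonical shorthand names to percentages of
total fatty acids. Canonical spelling is
`[anteiso-]C<carbons>:<double bonds>[ cis-<pos>[,<pos>…]][ n-<k>]`;
aliases (EPA, DHA, DPA) and typographic italics are normalized away at
parse time so every join uses one key. Omega families are restricted to
n-3, n-6 and n-4; the n-4 acid (C16:2 n-4) is carried as its own family
and excluded from n-3/n-6 sums. A bare `C18` is accepted as `C18:0`,
matching its abbreviated appearance in published coefficient tables.

Profile columns must total ≈100: totals outside 95–105 fail validation,
totals outside 99–101 only warn, because printed table columns carry
rounding (the bundled group-mean columns total 100.8–102.2). Units are
explicit everywhere: compositions in %, partial sums of lipid totals in
mg/g of edible portion, absolute fatty-acid quantities in mg/100 g.

## Lipid quality indices

The six indices are computed exactly as defined in the field literature
(see the module docstring of `codlipids.indices` for the formulas). Three
implementation decisions matter:

- **PI operates on fractions** (percent ÷ 100). Applied to raw
  percentages the weighted sum lands near 380 for these profiles, whereas
  the published index values are ~3.3–3.8; the ÷100 convention reproduces
  the published scale.
- **Missing formula terms contribute zero** with a logged notice. The AI
  formula names C12:0, which cod profiles rarely report.
- **Undefined ratios raise a typed `UndefinedIndexError`** instead of
  returning infinities; the batch driver converts them to missing values.

Two caveats are documented rather than "fixed". First, TI evaluated as
printed gives 0.147–0.190 on the bundled group means, about ten times the
published 0.015–0.019; the source of the published scaling is not
documented, so the formula is implemented as written and TI is excluded
from numeric agreement checks. Second, TI is not invariant under uniform
rescaling of the composition (its denominator adds the dimensionless
Σn-3/Σn-6 to percent-scale terms); it is well defined only for
compositions on a common total, which is how it is used.

## Cohort simulator

The published evidence is marginal: per-group mean ± SD per fatty acid
(n = 15 per origin), and mean ± SEM for lipid totals (SD recovered as
SEM·√n). The simulator draws each acid from a **normal distribution
truncated at zero**, by default **moment matched**: location and scale are
solved so the truncated distribution has exactly the printed mean and SD.
The solve is a 1-D Brent root find on ξ = μ/σ, since the truncated
coefficient of variation is strictly monotone in ξ; targets with SD ≥ mean
are unattainable (the truncated-normal CV is bounded by the exponential
limit of 1) and raise. The naive parameterization (location = mean,
scale = SD, then truncate) is available as `moment_match=False`; it
inflates realized means of heavily truncated acids by up to ~0.2·SD
(worst case in these tables: mean/SD ≈ 1.19), which is material when
checking parameter recovery against the printed targets — hence moment
matching as the default.

Dependence: acids are independent by default, because the tables carry no
covariances. An exchangeable Gaussian copula (`("exchangeable", ρ)`) is
provided for sensitivity analyses; correlated standard normals are pushed
through each acid's truncated-normal quantile function, so the marginals
are preserved exactly at any ρ.

Renormalization (default on) rescales each fish so its total equals the
group's mean column total, mirroring the rounded printed columns. Note
that renormalizing *adds* variance to acids with very tight printed SDs
(dividing by the noisy row total injects roughly `mean × CV(total)` of
extra SD — ~0.85 percentage points for a 21.9% acid with a 0.22 printed
SD); analyses that need the printed marginals exactly, such as the
discriminant benchmark below, should disable it.

Seeding: one root `SeedSequence` spawns one child stream per group, so
adding a group never perturbs earlier groups' draws, and equal seeds give
byte-identical cohorts.

**What the simulator does not emulate:** the true inter-FA correlation
structure (compositional closure, shared lipid-class biology), seasonal
and biological covariates, measurement error structure from duplicate GC
runs. Tests passing on synthetic cohorts therefore validate the
*machinery* (estimators, selection, cross-validation) under known truth;
they do not certify performance on real correlated profiles — see the
discriminant caveat below, where this distinction bites.

## Contrasts

One-way fixed-effects ANOVA with two planned orthogonal contrasts:
species (½, ½, −1) over (Norway, Iceland, Alaska), so the estimate is the
Atlantic-mean minus Pacific difference, and origin (1, −1, 0). The test is
the pooled-variance t: se = √(MSE·Σwᵢ²/nᵢ) on N − g degrees of freedom,
two-sided. With a single fixed effect and no random terms this coincides
with the mixed-model formulation the original analysis scripted. Printed
censored p-values (`<0.001`) are stored verbatim and parsed to 0.0009,
which preserves significance counts at any α ≥ 0.001. Simulation checks:
type-I error on null cohorts is 0.0485 over 2000 draws at α = 0.05, and
the Norway-vs-Iceland EPA difference is detected at p < 0.001 in 100/100
cohorts.

## Discriminant engine

Scatter matrices: T (total), W (pooled within), B = T − W, with T = W + B
exact by construction. The eigenproblem of W⁻¹B is solved in symmetrized
form — Cholesky W = LLᵀ, symmetric eigensolver on L⁻¹BL⁻ᵀ — for
stability; eigenvalues below 10⁻¹⁰·λ₁ are zeroed. There are exactly
min(g − 1, p) roots (two for three origins). Raw coefficients are scaled
to unit pooled within-class variance of the canonical variates;
standardized coefficients use pooled within-class SDs by default
(total-sample SDs selectable); each root is oriented so its
largest-magnitude standardized coefficient is positive, since the signs
are otherwise arbitrary.

Stepwise selection is greedy forward on Wilks' Λ = det(W)/det(T): the
candidate minimizing Λ of the augmented set enters iff its partial F,
((1 − Λr)/Λr)·((n − g − p)/(g − 1)) with Λr the Λ ratio and p the number
already entered, has p-value ≤ `slentry` (default 0.05). Ties break by
candidate order; singular candidate sets are skipped. On null cohorts the
per-candidate entry rate is ≈ the entry level (0.0525 measured at
slentry = 0.05 over 200 cohorts of 12 candidates).

Classification is the pooled-covariance linear rule with equal priors for
the three balanced groups; posteriors come from a log-sum-exp over the
linear scores, and ties break by group order. Leave-one-out
cross-validation refits the classifier (group means and pooled
covariance) for every held-out sample but keeps the variable set fixed,
matching the original pipeline in which selection preceded
cross-validation; refitting the selection per fold is available by
running `stepwise_select` inside a custom loop.

### The 100% benchmark and why independence falls short

On synthetic cohorts (15 fish/origin, the twelve published discriminant
variables, independent moment-matched marginals, seeds 1–10) the modal
leave-one-out accuracy is 93.3% (range 93.3–100%), not the 100% reported
for the real fish. This is a property of the data conditions, not the
estimator: per-fold predictions agree exactly with an independent LDA
implementation, and the errors concentrate on the Iceland/Alaska boundary
where the pooled-covariance assumption is most strained (printed
within-group SDs for C16:0 differ sixteen-fold across groups). A
sensitivity analysis with the exchangeable copula restores modal 100% at
ρ ≥ 0.4: the shared factor is removable by the discriminant projection,
so correlated noise of the kind real compositional data carry makes the
groups *more* separable than independent noise with the same marginal
SDs. The real fish were evidently in that regime; the printed tables do
not constrain it, so the default stays independent and the gap is
reported honestly.

The published canonical eigenvalues and coefficients likewise depend on
the unavailable per-fish covariance structure; they are treated as
qualitative targets only (two roots, first root dominant), and the
algebraic invariants (ρᵢ = √(λᵢ/(1+λᵢ)), Σλᵢ = tr(W⁻¹B), affine
invariance of canonical correlations) are verified instead.

## Problem sizes

The test suite and the acceptance script run the simulator at the study's
own scale (15 fish/origin) for pipeline checks, n = 500/origin for
parameter-recovery checks, n = 10⁴–2·10⁴ for truncation-bias checks, 200
null cohorts for stepwise calibration and 2000 for contrast type-I
calibration — sizes at which the binomial noise on the checked rates is
well inside the asserted bands.
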