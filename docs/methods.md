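# Methods

## Data-generating mechanism

All simulated data come from a linear-Gaussian structural equation system on
a DAG: with nodes ordered topologically, `X = B X + e`,
`e ~ N(0, diag(Ψ))`, so the implied covariance is
`Σ = (I−B)⁻¹ Ψ (I−B)⁻ᵀ`. The canonical graph is the three-node chain
`adiposity → inflammation → depression` with path coefficients

| chain | a (adiposity→protein) | b (protein→depression) | c′ (direct) |
|-------|----------------------|------------------------|-------------|
| IL-6  | .274                 | .125                   | 0           |
| CRP   | .429                 | .108                   | 0           |

These are the standardized path estimates from the mediation stage of the
empirical analysis the simulation mirrors; the direct adiposity→depression
path was null there, so `c_prime` defaults to 0 (it is configurable).

### Variance conventions

The coefficients above are standardized betas, but a simulation must also
pick residual variances, and that choice is not dictated by the
coefficients. Two conventions are implemented:

- **`unit_residual`** (default): all residual variances are 1 and the
  coefficients are used exactly as printed. Total variances then exceed 1
  (Var(M) = 1 + a²), and corr(A, M) = a/√(1+a²).
- **`standardized`**: `standardize_residuals` rescales Ψ so every implied
  total variance is exactly 1 (Ψ_M = 1 − a² for the chain). Under this
  convention the coefficients are exactly the standardized slopes that a
  z-scored regression recovers.

The default is `unit_residual` because it is the common default of SEM-style
simulation code for this model class and the published precision losses are
consistent with it. The adjusted model's asymptotic precision loss differs
between conventions — `100·a²/(1+a²)` (unit-residual: 6.98% IL-6, 15.54%
CRP) versus `100·a²` (standardized: 7.51%, 18.40%) — and
`analytic_precision_loss(a, convention)` exposes both closed forms as
oracles. Parameter-recovery checks of the mediation stage simulate from the
standardized convention, since only there do the z-scored sample slopes
target a and b exactly.

Noise is Gaussian only; the linear-Gaussian DGM is the model under study,
and no heavy-tailed option is provided.

## The two analysis models and the precision metric

Each replication draws one dataset of size N and fits two OLS models:
depression ~ inflammation (`unadjusted`) and
depression ~ inflammation + adiposity (`adjusted`); the focal quantity is
the inflammation coefficient. When c′ = 0 both estimators are consistent
for b — the unadjusted model is not misspecified because adiposity affects
depression only through inflammation — so adjustment changes no bias, only
variance. The finite-sample identity
`SE_adj²/SE_un² = (σ̂²_adj/σ̂²_un)/(1 − r̂²_AM)` (asserted in tests) is the
mechanism of the precision loss.

Performance metrics follow standard simulation-study practice:

- empirical SE = SD of estimates across replications (n−1 denominator),
  MCSE `empSE/√(2(n_reps−1))`;
- model SE = √(mean reported SE²);
- power = share of two-sided p < α, α = .05 throughout (the conventional
  level, consistent with the significance language of the reported results);
- relative precision gain vs the reference (unadjusted) method
  `100·((empSE_ref/empSE)² − 1)`, exactly 0 for the reference itself, with a
  leave-one-replication-out jackknife MCSE computed over the paired
  per-replication estimate streams. Its large-replication limit when c′ = 0
  is `−analytic_precision_loss(a, convention)`.
- the paired SE comparison is a paired t over d_r = SE_ref,r − SE_other,r;
  negative t means the non-reference SEs are larger. Degenerate inputs
  (zero empirical SE, constant differences) raise errors rather than
  returning infinities.

The expectation of the empirical-variance ratio carries a small
finite-sample offset: E[loss] ≈ r² + (1−r²)/(N−3), about +1 point at
N = 100 and negligible by N = 2000. For this reason the convergence check
against the analytic limit (±0.5 points at 100,000 replications) uses
N = 2000 per replication; the canonical study itself uses the design's
N ∈ {100, 250, 500}.

## Seeding

One integer master seed controls a whole study. Replication r of the
scenario at position s uses the integer
`SeedSequence(master_seed, spawn_key=(s, r)).generate_state(1)[0]`, so
scenarios can run in any order or in parallel with identical output and any
single replication can be regenerated in isolation. Failed replications
(rank-deficient designs, essentially impossible with continuous data) are
skipped, not resampled — resampling would bias the performance metrics —
and more than 1% failures aborts the scenario.

## Mediation stage

`fit_mediation` z-standardizes x, m, y (sample SD, n−1 denominator) after
listwise deletion over those three columns only, then fits `m ~ x` and
`y ~ m + x` by OLS; the indirect effect is a·b and a·b + c′ equals the
total x→y slope exactly (asserted to 1e-10). Standardizing first and
rescaling unstandardized slopes afterwards coincide for OLS; tests assert
this too. The CI is a percentile bootstrap: resample rows with replacement,
recompute the two slopes on the resample (without re-standardizing — the
statistic is the slope of the once-standardized data, as in common
macro implementations), and take empirical quantiles. Default 5,000
resamples at the conventional 95% level; both configurable, and the
bootstrap is chunked so memory stays bounded at large n. The
bias-corrected variants are deliberately out of scope; percentile is the
widely used default for this model class. p-values are two-sided t with
n − k − 1 df.

## Covariate-role classifier

`classify_covariate` works on reachability in the DAG: confounder if the
covariate reaches both exposure and outcome by directed paths avoiding the
exposure; mediator if it is a descendant of the exposure and ancestor of
the outcome; collider if a descendant of both; exposure-only ancestor if it
causes the exposure and every directed path to the outcome passes through
the exposure (the adiposity case — adjusting costs precision with no bias
benefit); outcome-only ancestor symmetrically; otherwise "disconnected".
The classifier is relative to a single (exposure, outcome) query; it does
not implement d-separation over arbitrary conditioning sets, latent
variables, or cyclic graphs (processes with feedback should be modelled as
separate per-timepoint DAGs).

## What the generator does and does not emulate

The synthetic data are exactly linear, exactly Gaussian, fully observed
(except where missingness is injected by the user), and cross-sectional.
Real biomarker data are right-skewed, measured with error, and partly
missing by design; depression scores are bounded sums of ordinal items.
Passing tests therefore demonstrate the *statistical mechanism* — the
variance inflation from adjusting for an exposure ancestor and its
magnitude given standardized effect sizes — not robustness of that
magnitude to distributional violations. Where empirical quantities depend
on the original cohort data (analytic n, scale reliability, the
significance of individual paths in real data), the package makes no claim;
only the printed standardized effect sizes enter as inputs.

## Problem sizes and determinism of checks

The bundled canonical configuration runs 6 scenarios × 1000 replications
(seed 20230629) in a few seconds. The test suite's stochastic checks use
fixed seeds throughout (hypothesis runs derandomized), with replication
counts chosen so each check's Monte Carlo error is small against its
tolerance: 1000 replications for directional/power orderings, 100,000 for
the analytic-limit convergence, 100 seeded replications for the
bootstrap-CI behaviour at the extraction-stage sample size (n = 549).
At 1000 replications the precision-loss statistic itself has a sampling SD
of roughly 1.7–2.5 points (it is a variance ratio and slightly
right-skewed), which is the dominant source of run-to-run spread in the
acceptance outputs.

## Known limitations

- Only simple (single-mediator, cross-sectional) mediation; no multiple or
  moderated mediation, no repeated measures.
- OLS with classical SEs only — no robust/sandwich SEs or GLMs; this
  matches the analysis models under study.
- The covariate classifier's label set collapses everything outside the
  five named roles (e.g. a pure descendant of the exposure alone) into
  "disconnected".
- Precision-loss asymptotics assume c′ = 0; with a nonzero direct path the
  unadjusted model is biased for b and the bias–variance trade-off must be
  weighed explicitly (the engine still runs such scenarios).
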