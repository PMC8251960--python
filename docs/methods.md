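# Methods

## Model and assumptions

Patients belong to one of two disjoint biomarker subgroups. Outcomes are
normally distributed with a common, known SD σ in every subgroup and arm;
randomization is 1:1 within each subgroup and stage. The treatment effect
θj in subgroup j is the mean difference between arms, tested one-sided
(H0j: θj ≤ 0). With rj·s·n patients of subgroup j in a stage of size s·n,
the effect estimate satisfies θ̂j ~ N(θj, 4σ²/(rj s n)) and its Z-value
Zj = θ̂j √(rj s n)/(2σ) is standard normal under the null. Stage-wise
statistics of the two subgroups are independent because the subgroups are
disjoint — no patient contributes to both; this independence is what lets
the intersection-test conditional error combine per-subgroup exceedance
probabilities multiplicatively.

Sample sizes are treated as continuous information fractions throughout:
rj·s·n need not be an integer. Only the patient-level simulation path
rounds to whole patients per arm, introducing an O(1/n) discrepancy that a
two-sample test cannot detect at the default n = 700.

### Testing

*Enrichment mode* controls the FWER by closed testing: individual level-α
tests (reject when Z ≥ Φ⁻¹(1−α)) plus a weighted Bonferroni intersection
test (reject when Z1 ≥ Φ⁻¹(1−ω1α) or Z2 ≥ Φ⁻¹(1−ω2α), ω1+ω2 = 1); global
rejection of H0j needs both. *Umbrella mode* tests each hypothesis at
level α with no adjustment. When a prevalence hits a boundary (r1 ∈ {0,1})
the unsampled subgroup's hypothesis is never rejected and its weight is
forced to the other subgroup (ω1 = 1 when r1 = 1, ω1 = 0 when r1 = 0).

*Two-stage designs* define a reference design that keeps prevalences and
weights unchanged and pools stages on the estimate scale
(θ̂⁽ᵖ⁾ = s⁽¹⁾θ̂⁽¹⁾ + s⁽²⁾θ̂⁽²⁾, equivalently Z⁽ᵖ⁾ = √s⁽¹⁾Z⁽¹⁾ + √s⁽²⁾Z⁽²⁾).
If the interim makes *any* change, the final tests use stage-2 data alone
at the conditional error rates A1, A2, A12 of the reference tests given
the stage-1 data. For the individual hypotheses this is an exact inversion
of the conditioning: Z⁽²⁾ > Φ⁻¹(1−A) is algebraically the pooled test, so
an "adaptation" that changes nothing gives identical individual decisions.
The intersection test's stage-2-only form differs from the pooled form
even at unchanged weights, so the reference pooled test is applied only
when the second-stage parameters equal the first-stage ones exactly
(tolerance 1e−12); any other value routes through the conditional-error
tests. Adaptive tests use a strict ">" and single-stage/pooled tests "≥" —
a measure-zero distinction fixed for determinism.

Degenerate levels are mapped without error: a threshold Φ⁻¹(1−p) with
p = 0 is +∞ (never reject), with p = 1 is −∞.

### Expected utilities

The utility of a completed trial is λ·1(reject H01) + (1−λ)·1(reject H02)
with λ the population prevalence of subgroup 1; a rejection in the larger
subgroup is worth more. Under the bivariate normal prior
θ ~ N(μ, Ψ) every layer of the optimization is an expectation of this
indicator utility under a bivariate normal law of Z-statistics, so all
closed-form utilities reduce to rectangle probabilities of the rejection
region {Z1 > b1 ∧ (Z1 > d1 ∨ Z2 > d2)} and its mirror image, assembled by
inclusion-exclusion from upper-orthant probabilities. This is exact — no
quadrature over θ is needed:

* *single-stage*: prior predictive Zj with mean cj μj, variance 1 + cj²ψj²,
  covariance c1c2ρψ1ψ2, cj = √(rj n)/(2σ); thresholds at levels α and ωjα;
* *interim (W2)*: posterior of θ by conjugate bivariate-normal update
  (covariance form V = Ψ − Ψ·(Ψ+D)⁻¹·Ψ restricted to sampled subgroups, so
  point-mass priors and one-armed stage-1 designs need no inverse of Ψ),
  then the stage-2 predictive Z-law with cj = √(rj⁽²⁾s⁽²⁾n)/(2σ) and
  thresholds at levels Aj and ωj⁽²⁾A12. The stage-2 sampling law uses the
  *adapted* prevalences.

The bivariate normal CDF is computed from Owen's T function
(`scipy.special.owens_t`), vectorized and accurate to ≈1e−14 (cross-checked
against `scipy.stats.multivariate_normal` in the test suite; the package
commits to ≤1e−8 absolute error). Exact zeros of the arguments are nudged
by 1e−13 to avoid the removable singularity of the Owen decomposition;
|ρ| ≥ 1 − 1e−12 and infinite thresholds take exact degenerate branches.
All probabilities are clipped to [0, 1].

## Optimization layers

1. **Single-stage** (r1, ω1): vectorized evaluation on a grid (default step
   0.01), then Hooke–Jeeves refinement from the best grid point, clipped to
   the unit box with the boundary weight coupling enforced at evaluation.
2. **Interim** (r1⁽²⁾, ω1⁽²⁾): Hooke–Jeeves pattern search (initial step
   0.25, shrink factor 0.5, parameter tolerance 1e−4), multi-started from
   the no-adaptation point and the four quadrant midpoints because the W2
   surface can be multimodal near the weight boundaries. The no-adaptation
   start guarantees gain ≥ 0 up to tolerance. If the attained maximum is
   below 0.01 the surface is flat at essentially zero (hopeless interim
   data), the optimization is flagged unstable and the no-adaptation
   parameters are returned.
3. **First stage** (s⁽¹⁾, r1⁽¹⁾, ω1⁽¹⁾): grid search (default s1 ∈
   {0.1,…,0.9}, r1 and ω1 ∈ {0,0.1,…,1}) scored by Monte-Carlo backward
   induction — draw θ from the prior, draw stage-1 estimates, optimize the
   interim decision and average the optimized W2 (default 1000 replicates
   per candidate). Common random numbers (the same prior and noise draws
   for every candidate) sharpen between-candidate comparisons without
   changing any estimand. Exact value ties break toward smaller s1, then
   r1 closer to λ — deterministic and documented here. A grid rather than
   a continuous search is used because the MC noise at ~1000 replicates
   makes a continuous argmax ill-posed.

A boundary subtlety worth knowing: with the closed test, a design that
keeps an arbitrarily small sliver of the unpromising subgroup retains a
level-α test of its hypothesis, whose rejections the utility rewards; the
expected utility is therefore discontinuous at r1 ∈ {0, 1} (where the
hypothesis is dropped) and the supremum can sit at the open boundary. The
optimizer reports the near-boundary argmax (e.g. r1 = 1 − 2e−5); tests and
reported optima treat values within grid resolution (0.01) of a boundary
as boundary designs.

## Simulation engine and the adaptation-rule map

Trials are simulated at the sufficient-statistic level (estimates drawn
directly from their sampling law); a patient-level path exists for
distributional fidelity checks. Operating characteristics
(per-hypothesis rejection probabilities, FWER, average utility, all with
standard errors) are estimated from n_sims replicates of a seeded
generator; the average utility is the λ-weighted mixture of the same
rejection indicators, so the identity avg_utility = λp1 + (1−λ)p2 holds
exactly by construction.

The optimal interim decision is a deterministic function of the stage-1
Z-values. Simulating 1e5 trials with a fresh pattern search per replicate
is wasteful, so `RuleMapPolicy` precomputes the decision on a Z-grid
(default 25×25 over [−4, 4]², warm-starting each point from its
neighbour's optimum) and interpolates bilinearly, letting the whole
simulation run vectorized. Because the conditional error principle
controls the type I error for *any* stage-1-measurable adaptation rule,
error-rate results under the interpolated rule are exact for that
(near-optimal) rule; utility and power results describe the same rule and
are indistinguishable from the exact rule's at the grid resolutions used.
Per-replicate exact optimization remains available
(`InterimOptimizedPolicy`) and is exercised in the tests.

Problem sizes used by the shipped studies: the acceptance report uses a
17-point-per-axis rule map and 100,000 replicates for the familywise error
rate; the test suite uses 13 points per axis, 50,000–100,000 replicates
for error rates, 20,000 for power curves, and 1e5–2e6 draws for
Monte-Carlo oracles.

## What the synthetic data do and do not emulate

The generator reproduces exactly the assumed sampling model: normal
endpoints, common known variance, 1:1 allocation, independent disjoint
subgroups, instantaneous outcome observation. It does not emulate unequal
or unknown variances, non-normal or delayed endpoints, recruitment
dynamics or screening delays, overlapping subgroups, or drift between
stages. Passing tests therefore validate the mathematics of the designs
under the stated model, not robustness to violations of it.

## Known limitations

* Two subgroups, two stages only; more general closures are out of scope.
* No futility stopping at the interim and no sample-size re-assessment;
  the utility has no cost term for patients enrolled.
* The utility rewards any global rejection, including rejections of a
  true null that survive the level-α filter (the boundary discontinuity
  above is one visible consequence).
* Estimation after adaptation (bias-adjusted point estimates, confidence
  regions) is not provided; the package's output is the test decision.
* The first-stage optimizer inherits Monte-Carlo noise; at the default
  1000 replicates per candidate, differences below ~0.01 in expected
  utility between neighbouring candidates are not resolved.
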