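# Methods

## Fixed-design sample sizes

Per-group sizes come from the standard normal-approximation formulas for
two independent groups. With effect `ε` (always treatment minus control),
margin `δ`, allocation ratio `k = n_T/n_C`, and variance terms
`V = p_T(1−p_T)/k + p_C(1−p_C)` (dichotomous) or `W = s²(1 + 1/k)`
(continuous), the control-group size is

| hypothesis            | numerator quantiles          | denominator   |
|-----------------------|------------------------------|---------------|
| equality              | `z_{1−α/2} + z_{1−β}`        | `ε²`          |
| non-inferiority, superiority | `z_{1−α} + z_{1−β}`   | `(ε − δ)²`    |
| equivalence           | `z_{1−α} + z_{1−β/2}`        | `(δ − |ε|)²`  |

times `V` (or `W`). Design choices:

* **Ceiling rounding, never nearest.** The reference dichotomous equality
  design (α=0.05, β=0.1, p_T=0.1, p_C=0.2, k=1) gives 262.69 → 263 per
  group, which fixes the convention.
* **Unpooled alternative-hypothesis variance** for dichotomous designs
  (`p_T(1−p_T)/k + p_C(1−p_C)`, not the pooled null variance); this is the
  form that reproduces 263 exactly.
* `ε` is never inferred from signs: `direction` (higher/lower outcome is
  better) is an explicit input, and margin signs are validated against it
  (non-inferiority: δ opposite in sign to the beneficial direction;
  superiority: same sign; equivalence: δ > 0 always).
* Degenerate specs that produce fewer than 2 per group are clamped to 2
  with a warning; zero denominators raise an infeasible-design error.

## Sequential boundary engine

Equally spaced looks are assumed throughout the solvers (the engine itself
accepts arbitrary strictly increasing information fractions ending at 1).
The sequential statistics are Markov on the partial-sum scale
`S_r = Z_r√t_r`, with independent increments
`N(θ(t_r − t_{r−1}), t_r − t_{r−1})`. The drift parameterization is
`θ = effect × √(maximum information)`, so the final-look statistic is
`N(θ, 1)` and `E[Z_r] = θ√t_r`.

Crossing probabilities use the classical recursion on the sub-density of
paths that have not yet stopped: the look-1 density is the normal density
truncated to the continuation region; each later look convolves it with
the increment kernel. Stopping mass is read off with *exact* normal tail
probabilities against the previous sub-density (not by integrating the new
density outside the bounds), which converges faster. Numerical choices:

* composite Simpson's rule on each continuation interval, 24 points per
  unit of `s` with a floor of 65 per interval (odd counts). Total
  rejection probabilities are stable to well below 1e-6 under refinement
  to 120 points per unit, against a per-probability target of 1e-5;
* no sub-density renormalization: lost mass *is* the stopping probability,
  and the bookkeeping invariant (rejections + early acceptances + mass
  reaching the final look undecided = 1) is asserted in tests;
* inner-wedge continuation regions are the two symmetric intervals
  `a_r√t_r ≤ |s| ≤ b_r√t_r`; futility bounds are truncated at zero, so the
  first look often has no futility stop at all;
* two-sided rejection throughout, both tails integrated under drift (no
  symmetry shortcut — under the alternative the "wrong-sign" tail is tiny
  but not zero).

**Constants.** `solve_constant` brackets the boundary constant between the
single-look quantile `z_{1−α/2}` and the Bonferroni quantile
`z_{1−α/(2R)}` and runs Brent's method to 1e-9 (the bracket is widened
downward for O'Brien–Fleming-type shapes, whose final bound can fall below
the single-look quantile). **Inflation.** With the boundary fixed, the
information scale ρ is Brent-solved on [1, 4] so that power at drift
`(z_{1−α/2}+z_{1−β})√ρ` equals `1−β`; a single look short-circuits to
ρ = 1. **Inner wedge.** The identity `θ_design = Cw1 + Cw2` ties the
design drift to the constants (and makes the boundaries meet at the final
look); a two-dimensional Powell-hybrid root-find imposes size α at drift 0
and power `1−β` at the design drift, with
`ρ = ((Cw1+Cw2)/(z_{1−α/2}+z_{1−β}))²`.

Sample-size adjustment multiplies the **rounded** fixed-design size by ρ
and takes the ceiling (263 × 1.199 → 316; inflating the unrounded 262.69
would give 315, so the base convention is observable and tested).

For the five-look reference design the solved Pocock inflation is
1.20647 — stable under grid refinement and confirmed by a 4×10⁶-path
Monte Carlo oracle (power 0.9001 at that value). Published tables print
1.207; the adjusted size ceil(263 × 1.20647) = 318 is unaffected.

## Interim statistics and decisions

* Dichotomous: `z_r = (p̂_T − p̂_C)/√((p̂_T(1−p̂_T) + p̂_C(1−p̂_C))/n_r)` —
  unpooled variance, matching the separate per-arm terms of the planning
  formulas. A pooled-variance variant would differ negligibly at design
  sizes but is not offered.
* Continuous: `z_r = (x̄_T − x̄_C)/√((s²_T + s²_C)/n_r)` with unbiased
  (n−1) sample variances — the standard estimator; at per-look sizes of
  60+ the n vs n−1 choice moves `z` by well under 1%.
* Both statistics require equal per-arm counts at each look; the CSV
  monitor truncates to the smaller arm with a warning on imbalance.
* Decision rule at look r < R: `|z| ≥ b_r` stops and rejects;
  `|z| < a_r` (inner wedge only) stops and accepts; otherwise continue.
  At look R, `|z| ≥ b_R` decides rejection, anything else acceptance.
  A monitoring session is single-use: after any stop verdict further
  looks raise an error rather than silently re-testing.

## Simulator

`simulate_trial` enrolls `ceil(r·n/R)` subjects per arm cumulatively,
computes each look's statistic with the same code the monitor applies to
real data, and applies the same decision rule. Each trial draws from its
own stream spawned by index from the master seed (`SeedSequence.spawn`),
so operating-characteristic runs are order-independent and reproducible.

The generator emulates idealized enrollment: independent outcomes,
instantaneous response, no dropout, no staggered entry, perfectly equal
and synchronous arm accrual. Passing simulation tests therefore verifies
the *mathematics* of the designs (size, power, expected sample size under
the normal approximation), not their robustness to the messiness of real
trials — attrition, overrunning, or time-varying effects are out of scope.

A look at which both Bernoulli arms are degenerate (all zeros or all
ones) has an undefined statistic; the simulator scores complete
separation as an infinite-|z| rejection and identical degenerate arms as
uninformative. At the design's per-look sizes this occurs with negligible
probability (~1e-13 at n=64, p=0.2) and does not move the estimated rates.

Default problem sizes: operating characteristics use 10⁵ replicates where
size/power are asserted (Monte Carlo SE ≈ 0.0007 at α = 0.05, ≈ 0.001 at
power 0.9), 10⁶ paths for the sequential-normal oracle, and smaller runs
for structural smoke tests. Bands in the tests are 3 MC standard errors
plus a 0.005 discreteness allowance for binomial outcomes where the
normal approximation is only asymptotic.

## Known limitations

* Looks must occur at equal information fractions; alpha-spending
  (calendar-time) schedules are deliberately not implemented.
* Normal-approximation statistics only — no exact binomial or t-based
  small-sample inference; designs with per-look arm sizes below ~30
  should be checked by simulation.
* Symmetric two-sided boundaries only; no asymmetric upper/lower designs,
  no survival or repeated-measures endpoints, no covariate adjustment.
* The annex-style table generator solves every grid cell from scratch;
  the full default grid (including the inner wedge's 270 two-dimensional
  solves) takes several minutes on one core.
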