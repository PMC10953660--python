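# gseqdesign

Planning and monitoring of parallel two-arm randomized clinical trials with
group-sequential interim analyses.

A trial that peeks at its data R times inflates its type I error unless the
per-look critical values are widened — and widening them costs power unless
the sample size grows. `gseqdesign` does both calculations from first
principles, for the four classical boundary families, and then applies and
verifies the resulting designs:

* **fixed-design sample sizes** for dichotomous and continuous outcomes
  under equality, non-inferiority, superiority and equivalence hypotheses
  (normal-approximation formulas, ceiling rounding, margin-sign validation);
* **group-sequential boundaries** — Pocock, O'Brien–Fleming, Wang–Tsiatis
  (shape Δ), and the inner wedge (efficacy *and* futility boundaries that
  meet at the final look) — solved by recursive numerical integration of the
  correlated sequential z statistics, together with the **sample-size
  inflation factor** each method requires;
* **interim monitoring**: standardized statistics from accumulating
  subject-level data and the per-look stop/continue decision rule;
* **Monte Carlo verification** of a design's operating characteristics
  (empirical size, power, stopping distribution, expected sample size).

It is aimed at biostatisticians and clinical-trial methodologists who want
the numbers a commercial package prints, but computed transparently.

## The model

At look r (information fraction `t_r = r/R`), the standardized statistic
`Z_r` of a two-arm comparison is approximately normal with
`E[Z_r] = θ√t_r` and `Corr(Z_i, Z_j) = √(t_i/t_j)`, where the drift θ is
the effect size times the square root of the maximum information. All four
boundary families are members of the Wang–Tsiatis power family

    b_r = C (r/R)^(Δ − 1/2)

with Δ = 0.5 (Pocock, flat), Δ = 0 (O'Brien–Fleming, `C√(R/r)`), free
Δ ∈ [0, 0.5] (Wang–Tsiatis), and for the inner wedge additionally a
futility boundary

    a_r = max(0, (Cw1 + Cw2)√(r/R) − Cw2 (r/R)^(Δ − 1/2))

that meets `b_r` at r = R. The constant C is root-found so that the total
null crossing probability is α; with the boundary fixed, the inflation
factor ρ is root-found so that the crossing probability at drift
`(z_{1−α/2} + z_{1−β})√ρ` is the target power. Crossing probabilities are
evaluated by the classical recursive sub-density integration on the
partial-sum scale (composite Simpson's rule); see `docs/methods.md`.

## Worked example

A dichotomous equality trial, α = 0.05, β = 0.1, death proportions 0.1
(treatment) vs 0.2 (control), equal allocation, monitored five times:

```sh
$ gseqdesign design --outcome dichotomous --hypothesis equality \
    --alpha 0.05 --beta 0.1 --p-treat 0.1 --p-control 0.2 \
    --method pocock --looks 5 --out report.json
n_control=263 n_treat=263
pocock: inflation=1.206 adjusted n per group=318
```

263 subjects per group suffice for a single final analysis; five Pocock
looks need 318 per group, each tested against the flat critical value
2.413. The same design under the inner wedge, which can also stop early
*for futility*:

```sh
$ gseqdesign boundaries --method iw --looks 5 --alpha 0.05 --beta 0.1 \
    --delta 0.25 --n-fixed 263
method=inner_wedge R=5 Delta=0.25
constant_efficacy=2.073 constant_futility=1.477
efficacy bounds: 3.099; 2.606; 2.355; 2.191; 2.073
futility bounds: 0.000; 0.388; 1.071; 1.613; 2.073
inflation=1.199
adjusted n per group=316
```

At the second look, `|z| ≥ 2.606` stops the trial for efficacy,
`|z| < 0.388` stops it for futility, anything between continues; the two
boundaries meet at 2.073 at the fifth look, where the trial must decide.
O'Brien–Fleming (`--method obf`, bounds 4.562 … 2.040, 270 per group) and
Wang–Tsiatis (`--method wt --delta 0.25`, bounds 3.194 … 2.136, 281 per
group) interpolate between spending error early and late.

The solved plan JSON feeds the other subcommands: `gseqdesign monitor
--plan plan.json --data trial.csv` applies the looks to real accumulating
data, `gseqdesign simulate --plan plan.json --pT 0.1 --pC 0.2 --nsim
100000 --seed 42` estimates the realized size/power by simulation, and
`gseqdesign tables --out DIR` regenerates the critical-value and
inflation-coefficient tables over a design grid. File formats are
described in `docs/formats.md`.

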