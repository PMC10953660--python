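# File formats

## Design config (`--config`, JSON or YAML)

Keys mirror `DesignSpec` field names exactly; CLI flags override config
values.

```json
{
  "outcome_type": "dichotomous",
  "hypothesis": "equality",
  "alpha": 0.05,
  "beta": 0.1,
  "p_treat": 0.1,
  "p_control": 0.2,
  "margin": 0.0,
  "alloc_ratio": 1.0,
  "direction": "higher_is_better"
}
```

Continuous designs use `mu_treat`, `mu_control`, `sd_pooled` instead of
the proportions.

## Design report (`gseqdesign design --out`, JSON)

Object with keys `spec` (the DesignSpec as above), `fixed`
(`n_control_raw`, `n_control`, `n_treat`), `plan` (a plan object, or
null for fixed-only designs) and `provenance` (`tool`, `version`,
`timestamp`, `config_hash`). `--format csv` writes the boundary table
instead; `--format text` a human-readable report. Regenerating a report
from the same config is bit-identical except for the timestamp.

## Plan (`plan.json`)

Written by `gseqdesign boundaries --out-json` and consumed by `monitor`
and `simulate`:

```json
{
  "method": "pocock",
  "num_looks": 5,
  "delta_shape": 0.5,
  "alpha": 0.05,
  "beta": 0.1,
  "constant_efficacy": 2.413,
  "constant_futility": null,
  "efficacy_bounds": [2.413, 2.413, 2.413, 2.413, 2.413],
  "futility_bounds": [],
  "inflation": 1.206,
  "n_adjusted_per_group": 318
}
```

`futility_bounds` is non-empty only for the inner wedge.

## Boundary table (CSV)

Columns `look, info_fraction, efficacy_bound, futility_bound`; the
futility column is empty/NaN for methods without early acceptance.

## Subject-level trial data (CSV)

One row per subject: `arm` (T or C), `outcome` (0/1 for dichotomous,
real for continuous), optional `enrollment_order` (integer; file order
is used when absent). Look r uses the first `ceil(r·n/R)` subjects of
each arm in enrollment order.

## Monitoring output (JSON lines)

One record per executed look:
`{"verdict": ..., "look_index": r, "z_value": ..., "efficacy_bound": ...,
"futility_bound": ...}` with verdicts `continue`, `stop_reject_H0`,
`stop_accept_H0`, `final_reject_H0`, `final_accept_H0`.

## Operating-characteristics report (`gseqdesign simulate`, JSON)

`n_simulations`, `reject_rate`, `reject_se` (binomial standard error),
`accept_early_rate`, `expected_n_per_group`, `stop_distribution`
(probability the trial concludes at each look; sums to 1).

## Coefficient tables (`gseqdesign tables`, CSV per method)

Columns `looks, alpha, power, critical_value, coef_fit` (plus `delta`
for Wang–Tsiatis; the inner wedge reports `Cw1, Cw2, coef_fit`), values
rounded to 3 decimals.

## Exit codes

0 success · 2 validation error · 3 solver failure · 4 I/O error.
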