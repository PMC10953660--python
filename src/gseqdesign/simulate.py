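"""Monte Carlo verification of group-sequential operating characteristics.

Simulates two-arm trials subject by subject, monitors them with the same
interim statistics and decision rules the monitoring module applies to
real data, and aggregates empirical size / power, early-stopping rates,
the stopping-time distribution and the expected per-group sample size.

Each simulated trial gets its own independent random stream, spawned from
the master seed by index, so results do not depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .boundaries import SequentialPlan
from .exceptions import InvalidSpecError, UndefinedStatisticError
from .monitor import (
    Decision,
    MonitoringSession,
    interim_z_continuous,
    interim_z_dichotomous,
)

__all__ = [
    "ArmModel",
    "OperatingCharacteristics",
    "simulate_trial",
    "operating_characteristics",
    "generate_trial_dataset",
]


@dataclass
class ArmModel:
    """Outcome distribution for one arm: Bernoulli(p) or Normal(mu, sd)."""

    kind: str  # "bernoulli" | "gaussian"
    p: Optional[float] = None
    mu: Optional[float] = None
    sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "bernoulli":
            if self.p is None or not 0.0 < self.p < 1.0:
                raise InvalidSpecError(f"bernoulli arm needs 0 < p < 1, got {self.p}")
        elif self.kind == "gaussian":
            if self.mu is None or self.sd is None or self.sd <= 0:
                raise InvalidSpecError("gaussian arm needs mu and sd > 0")
        else:
            raise InvalidSpecError(f"unknown arm kind {self.kind!r}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "bernoulli":
            return rng.binomial(1, self.p, size=n).astype(float)
        return rng.normal(self.mu, self.sd, size=n)


@dataclass
class OperatingCharacteristics:
    """Empirical behavior of a plan under given arm models."""

    n_simulations: int
    reject_rate: float
    reject_se: float
    accept_early_rate: float
    expected_n_per_group: float
    stop_distribution: np.ndarray  # P(trial concludes at look r), sums to 1

    def to_dict(self) -> dict:
        return {
            "n_simulations": self.n_simulations,
            "reject_rate": self.reject_rate,
            "reject_se": self.reject_se,
            "accept_early_rate": self.accept_early_rate,
            "expected_n_per_group": self.expected_n_per_group,
            "stop_distribution": [float(x) for x in self.stop_distribution],
        }


def _look_sizes(plan: SequentialPlan) -> list[int]:
    n, R = plan.n_adjusted_per_group, plan.num_looks
    return [math.ceil(r * n / R) for r in range(1, R + 1)]


def _rng_for_trial(seed: int | np.random.SeedSequence) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_trial(
    treat: ArmModel,
    control: ArmModel,
    plan: SequentialPlan,
    seed: int | np.random.SeedSequence,
) -> tuple[Decision, int, list[float]]:
    """Run one trial under the plan; deterministic given the seed.

    Subjects accumulate to ``ceil(r * n / R)`` per arm at look r.  Returns
    the terminal decision, the per-group sample size actually used, and
    the z value of every executed look.  A look whose statistic is
    degenerate (zero variance in both arms, possible only for extreme
    Bernoulli draws) is treated as uninformative and the trial continues.
    """
    if plan.n_adjusted_per_group <= 0:
        raise InvalidSpecError("plan has no adjusted sample size; solve it first")
    rng = _rng_for_trial(seed)
    sizes = _look_sizes(plan)
    n_max = sizes[-1]
    xt = treat.draw(n_max, rng)
    xc = control.draw(n_max, rng)
    dichotomous = treat.kind == "bernoulli"
    session = MonitoringSession(plan)
    z_values: list[float] = []
    decision: Decision | None = None
    for r, n_r in enumerate(sizes, start=1):
        try:
            if dichotomous:
                z = interim_z_dichotomous(
                    int(xt[:n_r].sum()), int(xc[:n_r].sum()), n_r
                )
            else:
                z = interim_z_continuous(xt[:n_r], xc[:n_r])
        except UndefinedStatisticError:
            # both arms degenerate: complete separation is overwhelming
            # evidence, identical degenerate arms are uninformative
            diff = float(xt[:n_r].mean() - xc[:n_r].mean())
            z = math.copysign(math.inf, diff) if diff != 0.0 else 0.0
        z_values.append(z)
        decision = session.look(z)
        if decision.verdict.is_stop:
            break
    return decision, sizes[decision.look_index - 1], z_values


def operating_characteristics(
    treat: ArmModel,
    control: ArmModel,
    plan: SequentialPlan,
    n_simulations: int,
    seed: int,
) -> OperatingCharacteristics:
    """Aggregate ``simulate_trial`` over independent streams."""
    if n_simulations < 1000:
        raise InvalidSpecError("use at least 1000 simulations for stable rates")
    streams = np.random.SeedSequence(seed).spawn(n_simulations)
    R = plan.num_looks
    rejected = 0
    accepted_early = 0
    stop_counts = np.zeros(R, dtype=np.int64)
    total_n = 0
    for ss in streams:
        decision, n_used, _ = simulate_trial(treat, control, plan, ss)
        if decision.verdict.value.endswith("reject_H0"):
            rejected += 1
        if decision.verdict.value == "stop_accept_H0":
            accepted_early += 1
        stop_counts[decision.look_index - 1] += 1
        total_n += n_used
    rate = rejected / n_simulations
    se = math.sqrt(max(rate * (1 - rate), 1e-12) / n_simulations)
    return OperatingCharacteristics(
        n_simulations=n_simulations,
        reject_rate=rate,
        reject_se=se,
        accept_early_rate=accepted_early / n_simulations,
        expected_n_per_group=total_n / n_simulations,
        stop_distribution=stop_counts / n_simulations,
    )


def generate_trial_dataset(
    treat: ArmModel,
    control: ArmModel,
    n_per_group: int,
    seed: int,
    path: str | Path,
) -> pd.DataFrame:
    """Write a subject-level trial CSV in the monitoring module's dialect.

    Rows alternate T/C in enrollment order; the frame written to ``path``
    is also returned.
    """
    rng = np.random.default_rng(seed)
    xt = treat.draw(n_per_group, rng)
    xc = control.draw(n_per_group, rng)
    rows = []
    order = 1
    for i in range(n_per_group):
        rows.append({"arm": "T", "outcome": xt[i], "enrollment_order": order})
        rows.append({"arm": "C", "outcome": xc[i], "enrollment_order": order + 1})
        order += 2
    df = pd.DataFrame(rows)
    if treat.kind == "bernoulli":
        df["outcome"] = df["outcome"].astype(int)
    try:
        df.to_csv(path, index=False)
    except OSError as err:
        raise OSError(f"failed to write trial dataset to {path}: {err}") from err
    return df
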