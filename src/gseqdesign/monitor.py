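"""Interim test statistics and sequential decision rules.

At look ``r`` with ``n_r`` subjects per arm, the standardized statistic is

* dichotomous: ``z_r = (pT - pC) / sqrt(pT(1-pT)/n_r + pC(1-pC)/n_r)`` with
  the estimated per-arm proportions (unpooled variance);
* continuous: ``z_r = (xbar_T - xbar_C) / sqrt(s2_T/n_r + s2_C/n_r)`` with
  unbiased (n-1 denominator) per-arm sample variances.

``|z_r|`` is compared against the plan's per-look boundaries: at or above
the efficacy bound the null is rejected and enrollment stops; strictly
below the futility bound (inner wedge only) the null is accepted early;
at the final look the efficacy bound alone decides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .boundaries import SequentialPlan
from .exceptions import (
    InvalidSpecError,
    MonitoringError,
    UndefinedStatisticError,
)

__all__ = [
    "Verdict",
    "InterimLook",
    "Decision",
    "interim_z_dichotomous",
    "interim_z_continuous",
    "apply_decision",
    "MonitoringSession",
    "read_trial_csv",
    "monitor_dataset",
]


class Verdict(str, Enum):
    CONTINUE = "continue"
    STOP_REJECT_H0 = "stop_reject_H0"
    STOP_ACCEPT_H0 = "stop_accept_H0"
    FINAL_REJECT_H0 = "final_reject_H0"
    FINAL_ACCEPT_H0 = "final_accept_H0"

    @property
    def is_stop(self) -> bool:
        return self != Verdict.CONTINUE


@dataclass
class InterimLook:
    """Per-arm data summary and standardized statistic at one look."""

    look_index: int
    n_per_group: int
    z_value: float
    p_hat_treat: Optional[float] = None
    p_hat_control: Optional[float] = None
    mean_treat: Optional[float] = None
    mean_control: Optional[float] = None
    var_treat: Optional[float] = None
    var_control: Optional[float] = None


@dataclass
class Decision:
    """The verdict of one executed look."""

    verdict: Verdict
    look_index: int
    z_value: float
    efficacy_bound: float
    futility_bound: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict.value,
            "look_index": self.look_index,
            "z_value": self.z_value,
            "efficacy_bound": self.efficacy_bound,
            "futility_bound": self.futility_bound,
        }


def interim_z_dichotomous(
    events_treat: int, events_control: int, n_per_group: int
) -> float:
    """Two-proportion z statistic at an interim look (unpooled variance)."""
    if n_per_group < 2:
        raise InvalidSpecError("need at least 2 subjects per arm")
    for ev in (events_treat, events_control):
        if not 0 <= ev <= n_per_group:
            raise InvalidSpecError(
                f"event count {ev} outside [0, {n_per_group}]"
            )
    pt = events_treat / n_per_group
    pc = events_control / n_per_group
    var = (pt * (1 - pt) + pc * (1 - pc)) / n_per_group
    if var == 0.0:
        raise UndefinedStatisticError(
            "both proportions are degenerate (0 or 1); z is undefined"
        )
    return (pt - pc) / math.sqrt(var)


def interim_z_continuous(
    values_treat: Sequence[float], values_control: Sequence[float]
) -> float:
    """Two-sample z statistic at an interim look (unbiased variances)."""
    xt = np.asarray(values_treat, dtype=float)
    xc = np.asarray(values_control, dtype=float)
    if xt.size != xc.size:
        raise InvalidSpecError("arms must have equal size at each look")
    n = xt.size
    if n < 2:
        raise InvalidSpecError("need at least 2 subjects per arm")
    var = (xt.var(ddof=1) + xc.var(ddof=1)) / n
    if var == 0.0:
        raise UndefinedStatisticError("zero variance in both arms; z is undefined")
    return float((xt.mean() - xc.mean()) / math.sqrt(var))


def apply_decision(
    z_value: float, look_index: int, plan: SequentialPlan
) -> Decision:
    """Apply the plan's stopping rule to the statistic of look ``look_index``."""
    R = plan.num_looks
    if not 1 <= look_index <= R:
        raise InvalidSpecError(f"look_index must lie in 1..{R}, got {look_index}")
    b = float(plan.efficacy_bounds[look_index - 1])
    has_futility = plan.futility_bounds.size > 0
    a = float(plan.futility_bounds[look_index - 1]) if has_futility else None
    final = look_index == R
    if abs(z_value) >= b:
        verdict = Verdict.FINAL_REJECT_H0 if final else Verdict.STOP_REJECT_H0
    elif final:
        verdict = Verdict.FINAL_ACCEPT_H0
    elif has_futility and abs(z_value) < a:
        verdict = Verdict.STOP_ACCEPT_H0
    else:
        verdict = Verdict.CONTINUE
    return Decision(
        verdict=verdict,
        look_index=look_index,
        z_value=float(z_value),
        efficacy_bound=b,
        futility_bound=a,
    )


class MonitoringSession:
    """Sequential looks against a plan; refuses looks after a stop.

    Looks must be executed in order 1, 2, ...; once any stopping verdict
    has been issued the session is closed and further looks raise
    :class:`MonitoringError`.
    """

    def __init__(self, plan: SequentialPlan):
        self.plan = plan
        self.decisions: list[Decision] = []
        self._stopped = False

    @property
    def stopped(self) -> bool:
        return self._stopped

    def look(self, z_value: float) -> Decision:
        if self._stopped:
            raise MonitoringError(
                "the trial has already stopped; no further looks are allowed"
            )
        r = len(self.decisions) + 1
        if r > self.plan.num_looks:
            raise MonitoringError("all planned looks have been executed")
        decision = apply_decision(z_value, r, self.plan)
        self.decisions.append(decision)
        if decision.verdict.is_stop:
            self._stopped = True
        return decision


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    """Read subject-level trial data.

    Expected columns: ``arm`` (values T/C), ``outcome`` (0/1 or real),
    optional ``enrollment_order`` (defaults to file order).  Rows are
    returned sorted by enrollment order.
    """
    df = pd.read_csv(path)
    missing = {"arm", "outcome"} - set(df.columns)
    if missing:
        raise InvalidSpecError(f"trial CSV lacks required columns: {sorted(missing)}")
    arms = set(df["arm"].astype(str).str.upper())
    if not arms <= {"T", "C"}:
        raise InvalidSpecError(f"arm labels must be T or C, found {sorted(arms)}")
    df = df.copy()
    df["arm"] = df["arm"].astype(str).str.upper()
    if "enrollment_order" in df.columns:
        df = df.sort_values("enrollment_order", kind="stable")
    return df.reset_index(drop=True)


def _look_sizes(plan: SequentialPlan) -> list[int]:
    n, R = plan.n_adjusted_per_group, plan.num_looks
    return [math.ceil(r * n / R) for r in range(1, R + 1)]


def monitor_dataset(
    plan: SequentialPlan,
    data: pd.DataFrame,
    dichotomous: Optional[bool] = None,
) -> list[Decision]:
    """Run all feasible looks of ``plan`` over accumulating subject data.

    Look ``r`` uses the first ``ceil(r * n / R)`` enrolled subjects of each
    arm; looks for which either arm has too few subjects are not executed.
    An imbalance between arms is truncated to the smaller count with a
    warning.  Monitoring stops at the first stopping verdict.
    """
    if plan.n_adjusted_per_group <= 0:
        raise InvalidSpecError("plan has no adjusted sample size; solve it first")
    treat = data.loc[data["arm"] == "T", "outcome"].to_numpy(dtype=float)
    control = data.loc[data["arm"] == "C", "outcome"].to_numpy(dtype=float)
    if len(treat) != len(control):
        warnings.warn(
            f"unequal arm sizes ({len(treat)} T vs {len(control)} C); "
            "truncating each look to the smaller arm",
            stacklevel=2,
        )
    available = min(len(treat), len(control))
    if dichotomous is None:
        dichotomous = bool(np.isin(np.concatenate([treat, control]), (0.0, 1.0)).all())
    session = MonitoringSession(plan)
    decisions: list[Decision] = []
    for n_r in _look_sizes(plan):
        if n_r > available:
            break
        if dichotomous:
            z = interim_z_dichotomous(
                int(treat[:n_r].sum()), int(control[:n_r].sum()), n_r
            )
        else:
            z = interim_z_continuous(treat[:n_r], control[:n_r])
        decision = session.look(z)
        decisions.append(decision)
        if decision.verdict.is_stop:
            break
    return decisions
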