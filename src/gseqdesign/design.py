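"""Fixed-design (single-look) sample sizes for two-arm parallel trials.

Implements the classical normal-approximation sample-size formulas for
comparing two independent groups on a dichotomous or continuous outcome,
under four hypothesis framings: equality (two-sided), non-inferiority,
superiority, and equivalence.

Notation
--------
``p_T, p_C``    event proportions in the treatment and control arms
``mu_T, mu_C``  outcome means (continuous outcome)
``s``           pooled standard deviation of the outcome
``eps``         the effect, always treatment minus control
``delta``       the non-inferiority / superiority / equivalence margin
``k``           allocation ratio ``n_T / n_C``
``z_q``         the q-quantile of the standard normal distribution

The control-arm size for a dichotomous outcome is, with
``V = p_T(1-p_T)/k + p_C(1-p_C)``:

=============== =====================================================
equality        ``(z_{1-a/2} + z_{1-b})^2 V / eps^2``
non-inf., sup.  ``(z_{1-a} + z_{1-b})^2 V / (eps - delta)^2``
equivalence     ``(z_{1-a} + z_{1-b/2})^2 V / (delta - |eps|)^2``
=============== =====================================================

and for a continuous outcome the same expressions with
``W = s^2 (1 + 1/k)`` in place of ``V``.  ``n_T = ceil(k * n_C_raw)``.
Per-group sizes are always rounded *up*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from scipy.stats import norm

from .exceptions import InfeasibleDesignError, InvalidSpecError

__all__ = [
    "OutcomeType",
    "Hypothesis",
    "Direction",
    "DesignSpec",
    "FixedDesign",
    "normal_quantile",
    "validate_margin_sign",
    "sample_size_dichotomous",
    "sample_size_continuous",
    "sample_size",
]


class OutcomeType(str, Enum):
    DICHOTOMOUS = "dichotomous"
    CONTINUOUS = "continuous"


class Hypothesis(str, Enum):
    EQUALITY = "equality"
    NONINFERIORITY = "noninferiority"
    SUPERIORITY = "superiority"
    EQUIVALENCE = "equivalence"


class Direction(str, Enum):
    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


def normal_quantile(q: float) -> float:
    """Standard-normal inverse CDF z_(q).

    Parameters
    ----------
    q : float
        Probability level, strictly inside (0, 1).

    Returns
    -------
    float
        The q-quantile of N(0, 1).
    """
    if not 0.0 < q < 1.0:
        raise InvalidSpecError(f"quantile level must lie in (0, 1), got {q!r}")
    return float(norm.ppf(q))


def validate_margin_sign(
    hypothesis: Hypothesis | str,
    direction: Direction | str,
    margin: float,
) -> tuple[bool, str]:
    """Check that the margin's sign is consistent with the hypothesis framing.

    Sign conventions (effect measured treatment minus control):

    * non-inferiority: ``delta < 0`` when higher outcomes are better,
      ``delta > 0`` when lower outcomes are better;
    * superiority: ``delta > 0`` when higher is better, ``delta < 0`` when
      lower is better;
    * equivalence: ``delta > 0`` always.

    Returns ``(True, "")`` when valid, otherwise ``(False, reason)``.
    """
    hypothesis = Hypothesis(hypothesis)
    direction = Direction(direction)
    if hypothesis == Hypothesis.EQUIVALENCE:
        if margin <= 0:
            return False, "equivalence margin must be strictly positive"
        return True, ""
    higher = direction == Direction.HIGHER_IS_BETTER
    if hypothesis == Hypothesis.NONINFERIORITY:
        ok = (margin < 0) if higher else (margin > 0)
        want = "negative" if higher else "positive"
    elif hypothesis == Hypothesis.SUPERIORITY:
        ok = (margin > 0) if higher else (margin < 0)
        want = "positive" if higher else "negative"
    else:
        raise InvalidSpecError(
            "margin-sign validation applies to noninferiority, superiority "
            "and equivalence hypotheses only"
        )
    if not ok:
        return False, (
            f"{hypothesis.value} margin must be {want} when direction is "
            f"{direction.value}, got {margin}"
        )
    return True, ""


@dataclass
class DesignSpec:
    """All planning inputs for a two-arm parallel trial.

    Dichotomous designs require ``p_treat``/``p_control``; continuous designs
    require ``mu_treat``/``mu_control``/``sd_pooled``.  ``margin`` is 0 for
    equality designs and carries the sign conventions enforced by
    :func:`validate_margin_sign` otherwise.
    """

    outcome_type: OutcomeType
    hypothesis: Hypothesis
    alpha: float
    beta: float
    p_treat: Optional[float] = None
    p_control: Optional[float] = None
    mu_treat: Optional[float] = None
    mu_control: Optional[float] = None
    sd_pooled: Optional[float] = None
    margin: float = 0.0
    alloc_ratio: float = 1.0
    direction: Direction = Direction.HIGHER_IS_BETTER

    def __post_init__(self) -> None:
        self.outcome_type = OutcomeType(self.outcome_type)
        self.hypothesis = Hypothesis(self.hypothesis)
        self.direction = Direction(self.direction)
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidSpecError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise InvalidSpecError(f"beta must lie in (0, 1), got {self.beta}")
        if not self.alloc_ratio > 0:
            raise InvalidSpecError(f"alloc_ratio must be > 0, got {self.alloc_ratio}")
        if self.outcome_type == OutcomeType.DICHOTOMOUS:
            for name in ("p_treat", "p_control"):
                p = getattr(self, name)
                if p is None:
                    raise InvalidSpecError(f"dichotomous design requires {name}")
                if not 0.0 < p < 1.0:
                    raise InvalidSpecError(f"{name} must lie in (0, 1), got {p}")
        else:
            for name in ("mu_treat", "mu_control", "sd_pooled"):
                if getattr(self, name) is None:
                    raise InvalidSpecError(f"continuous design requires {name}")
            if not self.sd_pooled > 0:
                raise InvalidSpecError(
                    f"sd_pooled must be > 0, got {self.sd_pooled}"
                )
        if self.hypothesis == Hypothesis.EQUALITY:
            if self.margin != 0.0:
                raise InvalidSpecError("equality designs take margin = 0")
        else:
            ok, reason = validate_margin_sign(
                self.hypothesis, self.direction, self.margin
            )
            if not ok:
                raise InvalidSpecError(reason)
        if self.hypothesis == Hypothesis.EQUIVALENCE:
            if not self.margin > abs(self.effect):
                raise InvalidSpecError(
                    "equivalence requires margin > |effect| "
                    f"(margin={self.margin}, effect={self.effect})"
                )

    @property
    def effect(self) -> float:
        """The design effect, treatment minus control."""
        if self.outcome_type == OutcomeType.DICHOTOMOUS:
            return self.p_treat - self.p_control
        return self.mu_treat - self.mu_control

    def to_dict(self) -> dict:
        return {
            "outcome_type": self.outcome_type.value,
            "hypothesis": self.hypothesis.value,
            "alpha": self.alpha,
            "beta": self.beta,
            "p_treat": self.p_treat,
            "p_control": self.p_control,
            "mu_treat": self.mu_treat,
            "mu_control": self.mu_control,
            "sd_pooled": self.sd_pooled,
            "margin": self.margin,
            "alloc_ratio": self.alloc_ratio,
            "direction": self.direction.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InvalidSpecError(f"unknown design fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class FixedDesign:
    """Per-group sizes of a single-look design.

    ``n_control_raw`` is the exact formula value; ``n_control`` and
    ``n_treat`` are the ceilings actually enrolled.
    """

    n_control_raw: float
    n_control: int
    n_treat: int
    spec: DesignSpec = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_control_raw": self.n_control_raw,
            "n_control": self.n_control,
            "n_treat": self.n_treat,
            "spec": self.spec.to_dict(),
        }


def _quantile_pair(spec: DesignSpec) -> tuple[float, float]:
    """The two normal quantiles entering the sample-size numerator."""
    if spec.hypothesis == Hypothesis.EQUALITY:
        return normal_quantile(1 - spec.alpha / 2), normal_quantile(1 - spec.beta)
    if spec.hypothesis == Hypothesis.EQUIVALENCE:
        return normal_quantile(1 - spec.alpha), normal_quantile(1 - spec.beta / 2)
    return normal_quantile(1 - spec.alpha), normal_quantile(1 - spec.beta)


def _denominator(spec: DesignSpec) -> float:
    eps = spec.effect
    if spec.hypothesis == Hypothesis.EQUALITY:
        if eps == 0.0:
            raise InfeasibleDesignError(
                "equality design with zero effect has no finite sample size"
            )
        return eps * eps
    if spec.hypothesis == Hypothesis.EQUIVALENCE:
        gap = spec.margin - abs(eps)
        if gap <= 0.0:
            raise InfeasibleDesignError(
                "equivalence design requires margin > |effect| "
                f"(margin={spec.margin}, effect={eps})"
            )
        return gap * gap
    gap = eps - spec.margin
    if gap == 0.0:
        raise InfeasibleDesignError(
            f"{spec.hypothesis.value} design with effect equal to the margin "
            "has no finite sample size"
        )
    return gap * gap


def _finish(spec: DesignSpec, n_c_raw: float) -> FixedDesign:
    n_control = math.ceil(n_c_raw)
    n_treat = math.ceil(spec.alloc_ratio * n_c_raw)
    if n_control < 2 or n_treat < 2:
        warnings.warn(
            "computed per-group size below 2; clamping — the specification is "
            "likely degenerate",
            stacklevel=3,
        )
        n_control = max(n_control, 2)
        n_treat = max(n_treat, 2)
    return FixedDesign(
        n_control_raw=n_c_raw, n_control=n_control, n_treat=n_treat, spec=spec
    )


def sample_size_dichotomous(spec: DesignSpec) -> FixedDesign:
    """Per-group sample sizes for a dichotomous outcome.

    Uses the unpooled alternative-hypothesis variance
    ``V = p_T(1-p_T)/k + p_C(1-p_C)``.
    """
    if spec.outcome_type != OutcomeType.DICHOTOMOUS:
        raise InvalidSpecError("spec is not a dichotomous design")
    z_a, z_b = _quantile_pair(spec)
    v = (
        spec.p_treat * (1 - spec.p_treat) / spec.alloc_ratio
        + spec.p_control * (1 - spec.p_control)
    )
    n_c_raw = (z_a + z_b) ** 2 * v / _denominator(spec)
    return _finish(spec, n_c_raw)


def sample_size_continuous(spec: DesignSpec) -> FixedDesign:
    """Per-group sample sizes for a continuous outcome.

    Uses ``W = s^2 (1 + 1/k)`` with a common standard deviation ``s``.
    """
    if spec.outcome_type != OutcomeType.CONTINUOUS:
        raise InvalidSpecError("spec is not a continuous design")
    z_a, z_b = _quantile_pair(spec)
    w = spec.sd_pooled**2 * (1 + 1 / spec.alloc_ratio)
    n_c_raw = (z_a + z_b) ** 2 * w / _denominator(spec)
    return _finish(spec, n_c_raw)


def sample_size(spec: DesignSpec) -> FixedDesign:
    """Dispatch to the dichotomous or continuous formula by outcome type."""
    if spec.outcome_type == OutcomeType.DICHOTOMOUS:
        return sample_size_dichotomous(spec)
    return sample_size_continuous(spec)
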