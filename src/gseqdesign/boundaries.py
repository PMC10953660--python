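"""Group-sequential stopping boundaries and sample-size inflation factors.

A two-arm trial analysed at information fractions ``t_1 < ... < t_R = 1``
produces standardized statistics ``Z_1, ..., Z_R`` that form a Gaussian
Markov sequence with ``Corr(Z_i, Z_j) = sqrt(t_i / t_j)`` and mean
``E[Z_r] = theta * sqrt(t_r)`` where ``theta`` is the *drift*: the effect
size times the square root of the maximum information (so the final-look
statistic is ``N(theta, 1)`` when ``t_R = 1``).

All four boundary families here are members of the Wang–Tsiatis power
family ``b_r = C * (r/R)^(Delta - 1/2)``:

* Pocock: ``Delta = 0.5`` — a flat critical value across looks;
* O'Brien–Fleming: ``Delta = 0`` — ``C * sqrt(R/r)``, very strict early;
* Wang–Tsiatis: any ``Delta`` in [0, 0.5];
* inner wedge: a power-family efficacy boundary ``b_r`` plus a futility
  boundary ``a_r = max(0, (Cw1 + Cw2) sqrt(r/R) - Cw2 (r/R)^(Delta-1/2))``
  that meets the efficacy boundary at the final look, allowing early
  acceptance of the null.

Boundary-crossing probabilities are computed by the classical recursive
sub-density integration on the partial-sum scale ``S_r = Z_r sqrt(t_r)``:
the increments ``S_r - S_{r-1}`` are independent
``N(theta (t_r - t_{r-1}), t_r - t_{r-1})``, so the sub-density of paths
still in play satisfies

    f_1(s) = phi((s - theta t_1) / sqrt(t_1)) / sqrt(t_1)
    f_r(s) = integral over the look-(r-1) continuation region of
             f_{r-1}(u) phi((s - u - theta dt) / sqrt(dt)) / sqrt(dt) du

with stopping mass read off through exact normal tail probabilities.
Integrals use composite Simpson's rule on each continuation interval; the
mass lost at each look *is* the stopping probability (no renormalization).

Solvers calibrate the boundary constant so total null rejection equals
alpha, and the sample-size *inflation factor* so that, with the boundary
fixed, total rejection at the design drift equals the target power.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, root
from scipy.stats import norm

from .design import FixedDesign, normal_quantile
from .exceptions import InvalidSpecError, SolverError

__all__ = [
    "Method",
    "SequentialPlan",
    "CrossingResult",
    "boundary_values",
    "crossing_probabilities",
    "solve_constant",
    "solve_inner_wedge",
    "inflation_factor",
    "adjust_sample_size",
    "solve_plan",
]

# Simpson quadrature resolution: points per unit of s, with a floor per
# continuation interval.  Both are comfortably past the ~1e-5 accuracy the
# solvers require.
_POINTS_PER_UNIT = 24
_MIN_POINTS = 65


class Method(str, Enum):
    POCOCK = "pocock"
    OBRIEN_FLEMING = "obrien_fleming"
    WANG_TSIATIS = "wang_tsiatis"
    INNER_WEDGE = "inner_wedge"

    @classmethod
    def parse(cls, name: "Method | str") -> "Method":
        if isinstance(name, cls):
            return name
        aliases = {
            "obf": cls.OBRIEN_FLEMING,
            "wt": cls.WANG_TSIATIS,
            "iw": cls.INNER_WEDGE,
        }
        key = str(name).strip().lower().replace("-", "_")
        if key in aliases:
            return aliases[key]
        try:
            return cls(key)
        except ValueError:
            raise InvalidSpecError(f"unknown boundary method {name!r}") from None


def _resolve_shape(method: Method, delta_shape: Optional[float]) -> float:
    """Power-family exponent Delta for a method; Pocock and OBF are fixed."""
    if method == Method.POCOCK:
        return 0.5
    if method == Method.OBRIEN_FLEMING:
        return 0.0
    if delta_shape is None:
        raise InvalidSpecError(f"{method.value} requires a shape parameter Delta")
    if not 0.0 <= delta_shape <= 0.5:
        raise InvalidSpecError(f"Delta must lie in [0, 0.5], got {delta_shape}")
    return float(delta_shape)


def boundary_values(
    method: Method | str,
    constant_efficacy: float,
    num_looks: int,
    delta_shape: Optional[float] = None,
    constant_futility: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-look boundaries from the method's solved constant(s).

    Returns ``(efficacy_bounds, futility_bounds)``; the futility vector is
    empty except for the inner wedge, whose futility boundary is truncated
    at zero and meets the efficacy boundary at the final look.
    """
    method = Method.parse(method)
    if num_looks < 1:
        raise InvalidSpecError("num_looks must be >= 1")
    if constant_efficacy <= 0:
        raise InvalidSpecError("efficacy constant must be positive")
    delta = _resolve_shape(method, delta_shape)
    frac = np.arange(1, num_looks + 1) / num_looks
    efficacy = constant_efficacy * frac ** (delta - 0.5)
    if method != Method.INNER_WEDGE:
        return efficacy, np.empty(0)
    if constant_futility is None or constant_futility < 0:
        raise InvalidSpecError("inner wedge requires a futility constant >= 0")
    futility = np.maximum(
        0.0,
        (constant_efficacy + constant_futility) * np.sqrt(frac)
        - constant_futility * frac ** (delta - 0.5),
    )
    return efficacy, futility


@dataclass
class CrossingResult:
    """Per-look stopping probabilities of a boundary at a given drift."""

    reject_prob_per_look: np.ndarray
    accept_prob_per_look: np.ndarray
    total_reject: float
    expected_info_fraction: float

    @property
    def total_accept_early(self) -> float:
        return float(self.accept_prob_per_look.sum())


def _simpson_grid(lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Simpson nodes and weights on [lo, hi] (odd point count)."""
    n = max(_MIN_POINTS, int(math.ceil((hi - lo) * _POINTS_PER_UNIT)) + 1)
    if n % 2 == 0:
        n += 1
    x = np.linspace(lo, hi, n)
    h = (hi - lo) / (n - 1)
    w = np.full(n, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return x, w * (h / 3.0)


def crossing_probabilities(
    efficacy_bounds: Sequence[float],
    futility_bounds: Sequence[float] | None,
    info_fractions: Sequence[float],
    drift: float,
) -> CrossingResult:
    """Stopping probabilities of a two-sided group-sequential boundary.

    Parameters
    ----------
    efficacy_bounds, futility_bounds
        Per-look thresholds on ``|Z_r|``; ``futility_bounds`` may be None
        or empty (no early acceptance).
    info_fractions
        Strictly increasing, ending at 1.
    drift
        ``theta = effect * sqrt(I_max)``: the mean of the final-look
        statistic, so ``E[Z_r] = drift * sqrt(t_r)``.

    The trial rejects at look r when ``|Z_r| >= efficacy_bounds[r]`` and
    (inner wedge only) accepts early when ``|Z_r| < futility_bounds[r]``.
    """
    b = np.asarray(efficacy_bounds, dtype=float)
    t = np.asarray(info_fractions, dtype=float)
    R = b.size
    if t.size != R:
        raise InvalidSpecError("info_fractions and bounds must have equal length")
    if np.any(np.diff(t) <= 0) or t[0] <= 0 or abs(t[-1] - 1.0) > 1e-12:
        raise InvalidSpecError(
            "info_fractions must be strictly increasing and end at 1"
        )
    if futility_bounds is None or len(futility_bounds) == 0:
        a = np.zeros(R)
    else:
        a = np.asarray(futility_bounds, dtype=float)
        if a.size != R:
            raise InvalidSpecError("futility_bounds length must equal num_looks")
        if np.any(a < 0) or np.any(a[:-1] >= b[:-1]):
            raise InvalidSpecError(
                "futility bounds must be >= 0 and below efficacy bounds "
                "before the final look"
            )

    # Work on the partial-sum scale S_r = Z_r * sqrt(t_r).
    B = b * np.sqrt(t)  # efficacy on the S scale
    A = a * np.sqrt(t)  # futility on the S scale

    reject = np.zeros(R)
    accept = np.zeros(R)

    # Look 1: S_1 ~ N(drift * t_1, t_1).
    sd1 = math.sqrt(t[0])
    m1 = drift * t[0]
    reject[0] = norm.cdf((-B[0] - m1) / sd1) + norm.sf((B[0] - m1) / sd1)
    if A[0] > 0:
        accept[0] = norm.cdf((A[0] - m1) / sd1) - norm.cdf((-A[0] - m1) / sd1)

    def continuation_intervals(r: int) -> list[tuple[float, float]]:
        if A[r] > 0:
            return [(-B[r], -A[r]), (A[r], B[r])]
        return [(-B[r], B[r])]

    nodes: np.ndarray | None = None
    dens: np.ndarray | None = None
    wts: np.ndarray | None = None
    if R > 1:
        parts = [_simpson_grid(lo, hi) for lo, hi in continuation_intervals(0)]
        nodes = np.concatenate([p[0] for p in parts])
        wts = np.concatenate([p[1] for p in parts])
        dens = norm.pdf((nodes - m1) / sd1) / sd1

    for r in range(1, R):
        dt = t[r] - t[r - 1]
        sd = math.sqrt(dt)
        mu = drift * dt
        # Stopping mass at look r, integrating exact normal tails over the
        # previous continuation sub-density.
        upper = norm.sf((B[r] - nodes - mu) / sd)
        lower = norm.cdf((-B[r] - nodes - mu) / sd)
        reject[r] = float(np.sum(wts * dens * (upper + lower)))
        if A[r] > 0:
            # at the final look the wedge closes (a_R = b_R): everything
            # not rejected is accepted, so this is the full inner mass
            inner = norm.cdf((A[r] - nodes - mu) / sd) - norm.cdf(
                (-A[r] - nodes - mu) / sd
            )
            accept[r] = float(np.sum(wts * dens * inner))
        if r < R - 1:
            parts = [_simpson_grid(lo, hi) for lo, hi in continuation_intervals(r)]
            new_nodes = np.concatenate([p[0] for p in parts])
            new_wts = np.concatenate([p[1] for p in parts])
            kernel = norm.pdf((new_nodes[:, None] - nodes[None, :] - mu) / sd) / sd
            dens = kernel @ (wts * dens)
            nodes, wts = new_nodes, new_wts

    total_reject = float(reject.sum())
    stopped_early = reject[:-1].sum() + accept[:-1].sum() if R > 1 else 0.0
    expected_t = float(np.sum(t[:-1] * (reject[:-1] + accept[:-1])) + t[-1] * (1.0 - stopped_early))
    return CrossingResult(
        reject_prob_per_look=reject,
        accept_prob_per_look=accept,
        total_reject=total_reject,
        expected_info_fraction=expected_t,
    )


def _equal_fractions(num_looks: int) -> np.ndarray:
    return np.arange(1, num_looks + 1) / num_looks


def solve_constant(
    method: Method | str,
    num_looks: int,
    alpha: float,
    delta_shape: Optional[float] = None,
) -> float:
    """Boundary constant giving overall two-sided size alpha.

    Root-finds C so that the total null crossing probability of the
    power-family bounds over equally spaced looks equals alpha.  Both
    bracket endpoints are provable bounds: the single-look quantile
    ``z_{1-alpha/2}`` from below and the Bonferroni quantile
    ``z_{1-alpha/(2R)}`` from above.
    """
    method = Method.parse(method)
    if method == Method.INNER_WEDGE:
        raise InvalidSpecError(
            "the inner wedge couples size and power; use solve_inner_wedge"
        )
    if not 0.0 < alpha < 1.0:
        raise InvalidSpecError(f"alpha must lie in (0, 1), got {alpha}")
    delta = _resolve_shape(method, delta_shape)
    t = _equal_fractions(num_looks)
    if num_looks == 1:
        return normal_quantile(1 - alpha / 2)

    def excess(c: float) -> float:
        eff, _ = boundary_values(method, c, num_looks, delta)
        return crossing_probabilities(eff, None, t, 0.0).total_reject - alpha

    lo = normal_quantile(1 - alpha / 2)
    hi = normal_quantile(1 - alpha / (2 * num_looks))
    # OBF-type bounds spend so little alpha early that the final bound can
    # sit below the single-look quantile; widen the bracket if needed.
    while excess(lo) < 0 and lo > 0.5:
        lo -= 0.25
    while excess(hi) > 0:
        hi += 0.5
        if hi > 20:
            raise SolverError("failed to bracket the boundary constant")
    try:
        return float(brentq(excess, lo, hi, xtol=1e-9))
    except Exception as err:  # pragma: no cover - bracketing guarded above
        raise SolverError(f"constant root-find failed: {err}") from err


def inflation_factor(
    method: Method | str,
    num_looks: int,
    alpha: float,
    beta: float,
    delta_shape: Optional[float] = None,
) -> float:
    """Sample-size inflation preserving power 1 - beta under the boundary.

    For Pocock / O'Brien–Fleming / Wang–Tsiatis: with the size-alpha
    constant fixed, root-find the information scale rho such that total
    rejection at drift ``(z_{1-alpha/2} + z_{1-beta}) * sqrt(rho)`` equals
    ``1 - beta``.  The fixed design needs drift ``z_{1-alpha/2}+z_{1-beta}``
    exactly, so rho is the factor by which the sample size must grow.
    For the inner wedge, delegates to :func:`solve_inner_wedge`.
    """
    method = Method.parse(method)
    if method == Method.INNER_WEDGE:
        return solve_inner_wedge(num_looks, alpha, beta, delta_shape)[2]
    if not 0.0 < beta < 1.0:
        raise InvalidSpecError(f"beta must lie in (0, 1), got {beta}")
    if num_looks == 1:
        return 1.0
    delta = _resolve_shape(method, delta_shape)
    c = solve_constant(method, num_looks, alpha, delta)
    eff, _ = boundary_values(method, c, num_looks, delta)
    t = _equal_fractions(num_looks)
    base_drift = normal_quantile(1 - alpha / 2) + normal_quantile(1 - beta)
    target = 1.0 - beta

    def shortfall(rho: float) -> float:
        res = crossing_probabilities(eff, None, t, base_drift * math.sqrt(rho))
        return res.total_reject - target

    lo, hi = 1.0, 4.0
    if shortfall(lo) >= 0:
        # Repeated looks can only lose power, so this is numerically ~0.
        return 1.0
    try:
        return float(brentq(shortfall, lo, hi, xtol=1e-9))
    except Exception as err:
        raise SolverError(f"inflation root-find failed: {err}") from err


def solve_inner_wedge(
    num_looks: int,
    alpha: float,
    beta: float,
    delta_shape: Optional[float] = None,
) -> tuple[float, float, float]:
    """Jointly solve the inner-wedge constants (Cw1, Cw2) and inflation.

    The design drift is tied to the constants by ``theta = Cw1 + Cw2``,
    which makes the futility and efficacy boundaries meet at the final
    look.  The pair is root-found so that total rejection equals alpha at
    drift 0 and ``1 - beta`` at the design drift; the inflation is then
    ``((Cw1 + Cw2) / (z_{1-alpha/2} + z_{1-beta}))^2``.
    """
    if not 0.0 < alpha < 1.0 or not 0.0 < beta < 1.0:
        raise InvalidSpecError("alpha and beta must lie in (0, 1)")
    delta = _resolve_shape(Method.INNER_WEDGE, delta_shape)
    z_a2 = normal_quantile(1 - alpha / 2)
    z_b = normal_quantile(1 - beta)
    if num_looks == 1:
        return z_a2, z_b, 1.0
    t = _equal_fractions(num_looks)

    def residuals(x: np.ndarray) -> np.ndarray:
        cw1, cw2 = float(x[0]), float(x[1])
        if cw1 <= 0 or cw2 < 0:
            return np.array([1.0, 1.0])
        eff, fut = boundary_values(
            Method.INNER_WEDGE, cw1, num_looks, delta, constant_futility=cw2
        )
        size = crossing_probabilities(eff, fut, t, 0.0).total_reject
        power = crossing_probabilities(eff, fut, t, cw1 + cw2).total_reject
        return np.array([size - alpha, power - (1.0 - beta)])

    sol = root(residuals, x0=np.array([z_a2 * 1.05, z_b * 1.1]), method="hybr",
               options={"xtol": 1e-10})
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise SolverError(f"inner-wedge solve did not converge: {sol.message}")
    cw1, cw2 = float(sol.x[0]), float(sol.x[1])
    inflation = ((cw1 + cw2) / (z_a2 + z_b)) ** 2
    return cw1, cw2, inflation


def adjust_sample_size(fixed: FixedDesign | int, inflation: float) -> int:
    """Inflate a fixed-design per-group size for sequential monitoring.

    The base is the *rounded* fixed-design size (e.g. 263, not 262.68),
    and the product is rounded up.
    """
    if inflation < 1.0 - 1e-9:
        raise InvalidSpecError(f"inflation must be >= 1, got {inflation}")
    n = fixed.n_control if isinstance(fixed, FixedDesign) else int(fixed)
    return math.ceil(n * inflation - 1e-9)


@dataclass
class SequentialPlan:
    """A fully solved group-sequential design, ready for monitoring."""

    method: Method
    num_looks: int
    delta_shape: float
    alpha: float
    beta: float
    constant_efficacy: float
    efficacy_bounds: np.ndarray
    inflation: float
    n_adjusted_per_group: int
    constant_futility: Optional[float] = None
    futility_bounds: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def info_fractions(self) -> np.ndarray:
        return _equal_fractions(self.num_looks)

    def to_dict(self) -> dict:
        return {
            "method": self.method.value,
            "num_looks": self.num_looks,
            "delta_shape": self.delta_shape,
            "alpha": self.alpha,
            "beta": self.beta,
            "constant_efficacy": self.constant_efficacy,
            "constant_futility": self.constant_futility,
            "efficacy_bounds": [float(x) for x in self.efficacy_bounds],
            "futility_bounds": [float(x) for x in self.futility_bounds],
            "inflation": self.inflation,
            "n_adjusted_per_group": self.n_adjusted_per_group,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SequentialPlan":
        return cls(
            method=Method.parse(d["method"]),
            num_looks=int(d["num_looks"]),
            delta_shape=float(d["delta_shape"]),
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            constant_efficacy=float(d["constant_efficacy"]),
            constant_futility=(
                None if d.get("constant_futility") is None
                else float(d["constant_futility"])
            ),
            efficacy_bounds=np.asarray(d["efficacy_bounds"], dtype=float),
            futility_bounds=np.asarray(d.get("futility_bounds", []), dtype=float),
            inflation=float(d["inflation"]),
            n_adjusted_per_group=int(d["n_adjusted_per_group"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SequentialPlan":
        return cls.from_dict(json.loads(Path(path).read_text()))


def solve_plan(
    method: Method | str,
    num_looks: int,
    alpha: float,
    beta: float,
    delta_shape: Optional[float] = None,
    fixed: FixedDesign | int | None = None,
) -> SequentialPlan:
    """Solve constants, boundaries, inflation and (optionally) adjusted n.

    ``fixed`` is the fixed-design per-group size to inflate; when omitted,
    ``n_adjusted_per_group`` is set to 0 and must be filled in before the
    plan can drive monitoring or simulation.
    """
    method = Method.parse(method)
    delta = _resolve_shape(method, delta_shape)
    if method == Method.INNER_WEDGE:
        cw1, cw2, inflation = solve_inner_wedge(num_looks, alpha, beta, delta)
        eff, fut = boundary_values(
            method, cw1, num_looks, delta, constant_futility=cw2
        )
        c, c_fut = cw1, cw2
    else:
        c = solve_constant(method, num_looks, alpha, delta)
        inflation = inflation_factor(method, num_looks, alpha, beta, delta)
        eff, fut = boundary_values(method, c, num_looks, delta)
        c_fut = None
    n_adj = 0 if fixed is None else adjust_sample_size(fixed, inflation)
    return SequentialPlan(
        method=method,
        num_looks=num_looks,
        delta_shape=delta,
        alpha=alpha,
        beta=beta,
        constant_efficacy=c,
        constant_futility=c_fut,
        efficacy_bounds=eff,
        futility_bounds=fut,
        inflation=inflation,
        n_adjusted_per_group=n_adj,
    )
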