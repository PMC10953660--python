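"""Design reports: assembling, serializing and rendering planning output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .boundaries import Method, SequentialPlan, solve_plan
from .design import DesignSpec, FixedDesign, sample_size
from .exceptions import InvalidSpecError

__all__ = ["DesignReport", "run_design", "render_report", "load_config", "boundary_table"]


def load_config(path: str | Path) -> dict:
    """Read a JSON or YAML config whose keys mirror DesignSpec field names."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise InvalidSpecError("config file must contain a mapping")
    return data


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DesignReport:
    """A fixed design plus (optionally) its sequential plan, with provenance."""

    spec: DesignSpec
    fixed: FixedDesign
    plan: Optional[SequentialPlan]
    version: str
    timestamp: str
    config_hash: str

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "fixed": self.fixed.to_dict(),
            "plan": None if self.plan is None else self.plan.to_dict(),
            "provenance": {
                "tool": "gseqdesign",
                "version": self.version,
                "timestamp": self.timestamp,
                "config_hash": self.config_hash,
            },
        }


def run_design(
    spec: DesignSpec,
    method: Method | str | None = None,
    num_looks: int | None = None,
    delta_shape: float | None = None,
) -> DesignReport:
    """Compute the fixed design and, when a method is given, the solved plan."""
    fixed = sample_size(spec)
    plan = None
    if method is not None:
        if num_looks is None:
            raise InvalidSpecError("a sequential method requires --looks")
        plan = solve_plan(
            method, num_looks, spec.alpha, spec.beta, delta_shape, fixed=fixed
        )
    payload = spec.to_dict()
    payload.update(method=None if method is None else Method.parse(method).value,
                   num_looks=num_looks, delta_shape=delta_shape)
    return DesignReport(
        spec=spec,
        fixed=fixed,
        plan=plan,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        config_hash=_config_hash(payload),
    )


def boundary_table(plan: SequentialPlan) -> pd.DataFrame:
    """Per-look boundary table: look, info_fraction, efficacy, futility."""
    has_fut = plan.futility_bounds.size > 0
    return pd.DataFrame(
        {
            "look": range(1, plan.num_looks + 1),
            "info_fraction": plan.info_fractions,
            "efficacy_bound": plan.efficacy_bounds,
            "futility_bound": plan.futility_bounds if has_fut else float("nan"),
        }
    )


def render_report(report: DesignReport, format: str, out: str | Path) -> list[Path]:
    """Write the report as json, csv (boundary table) or human-readable text.

    ``out`` is the destination path; for csv with no plan an empty table is
    refused.  Returns the paths written.
    """
    out = Path(out)
    if format == "json":
        out.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        return [out]
    if format == "csv":
        if report.plan is None:
            raise InvalidSpecError("no sequential plan: nothing to tabulate as csv")
        boundary_table(report.plan).to_csv(out, index=False, float_format="%.6f")
        return [out]
    if format == "text":
        out.write_text(_render_text(report))
        return [out]
    raise InvalidSpecError(f"unknown report format {format!r}")


def _render_text(report: DesignReport) -> str:
    s, f = report.spec, report.fixed
    lines = [
        "gseqdesign design report",
        f"  outcome: {s.outcome_type.value}   hypothesis: {s.hypothesis.value}",
        f"  alpha={s.alpha}  beta={s.beta}  allocation k={s.alloc_ratio}",
        f"  effect (T-C): {s.effect:g}   margin: {s.margin:g}",
        f"  fixed design: n_control={f.n_control}  n_treat={f.n_treat}"
        f"  (raw {f.n_control_raw:.2f})",
    ]
    plan = report.plan
    if plan is not None:
        lines += [
            "",
            f"  sequential plan: {plan.method.value}, R={plan.num_looks}, "
            f"Delta={plan.delta_shape:g}",
            f"  inflation factor: {plan.inflation:.3f}   "
            f"adjusted n per group: {plan.n_adjusted_per_group}",
            "",
            "  look  info_frac  efficacy_bound  futility_bound",
        ]
        for _, row in boundary_table(plan).iterrows():
            fut = "" if pd.isna(row["futility_bound"]) else f"{row['futility_bound']:.3f}"
            lines.append(
                f"  {int(row['look']):>4}  {row['info_fraction']:>9.2f}  "
                f"{row['efficacy_bound']:>14.3f}  {fut:>14}"
            )
    return "\n".join(lines) + "\n"
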