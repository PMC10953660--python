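"""Exception hierarchy for gseqdesign.

The CLI maps these onto exit codes: validation problems exit 2, solver
failures exit 3, I/O failures exit 4.
"""


class GseqError(Exception):
    """Base class for all gseqdesign errors."""


class InvalidSpecError(GseqError, ValueError):
    """A design specification violates a domain invariant."""


class InfeasibleDesignError(GseqError, ValueError):
    """The requested design has no finite sample size (degenerate denominator)."""


class SolverError(GseqError, RuntimeError):
    """A boundary or inflation root-find failed to converge or bracket."""


class UndefinedStatisticError(GseqError, ValueError):
    """The interim test statistic is undefined (zero variance in both arms)."""


class MonitoringError(GseqError, RuntimeError):
    """Illegal monitoring operation, e.g. a look after a stopping decision."""
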