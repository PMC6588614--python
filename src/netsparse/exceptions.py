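"""Exception types shared across the package."""


class NetsparseError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGraphError(NetsparseError):
    """Raised when a graph admits no legal rewiring move."""


class UndefinedMetricError(NetsparseError):
    """Raised when a topology metric is undefined for the input (e.g. no edges)."""


class ClosedLoopUnstableError(NetsparseError):
    """Raised when the closed loop -(L + F) is not Hurwitz, so the H2 cost diverges."""


class InfeasiblePatternError(NetsparseError):
    """Raised when no stabilizing feedback gain exists on a sparsity pattern."""
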