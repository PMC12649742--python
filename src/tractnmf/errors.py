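"""Exception types shared across the package.

Most derive from :class:`ValueError` so callers can catch broadly; the
specific classes exist so tests and pipelines can distinguish bad user
specifications from degenerate data.
"""


class TractNMFError(Exception):
    """Base class for package-specific errors."""


class InvalidSpecError(TractNMFError, ValueError):
    """A cohort/geometry/pipeline specification violates its contract."""


class DomainError(TractNMFError, ValueError):
    """Data outside the mathematical domain of an operation (e.g. negative
    entries in a nonnegative matrix, unknown hemisphere label)."""


class ShapeError(TractNMFError, ValueError):
    """Conformability failure between arrays and the geometry they reference."""


class InvalidMaskError(TractNMFError, ValueError):
    """A vertex mask is empty or violates a required containment relation."""


class UndefinedStatisticError(TractNMFError, ValueError):
    """A statistic is undefined for the given input (zero variance, zero
    prefrontal mass, zero-norm reference)."""


class UnbalancedDesignError(TractNMFError, ValueError):
    """Nested-ANOVA input is not a balanced design; only balanced designs
    are supported."""


class InvalidDesignError(TractNMFError, ValueError):
    """Fewer groups/subgroups/replicates than the analysis requires."""


class MetadataError(TractNMFError, ValueError):
    """A required sidecar or metadata field is missing on disk."""
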