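"""Exception hierarchy for the sexprs pipeline.

All pipeline errors derive from :class:`SexPRSError` so callers can catch one
base class; most also derive from the closest builtin (ValueError) so that
generic error handling keeps working.
"""


class SexPRSError(Exception):
    """Base class for all sexprs errors."""


class ConfigurationError(SexPRSError, ValueError):
    """A scenario / cohort / grid configuration is invalid."""


class DomainError(SexPRSError, ValueError):
    """A numeric parameter is outside its mathematical domain."""


class InsufficientSamplesError(ConfigurationError):
    """A cohort request exceeds the individuals available."""


class DegenerateInputError(SexPRSError, ValueError):
    """An input is formally valid but makes the requested estimate undefined."""


class InfeasibleArchitectureError(ConfigurationError):
    """Requested causal-set sizes cannot be drawn from the variant panel."""


class AlignmentError(SexPRSError, ValueError):
    """Variant identifiers or alleles cannot be reconciled between inputs."""


class FormatError(SexPRSError, ValueError):
    """A summary-statistics or weight file violates the exchange format."""


class SolverError(SexPRSError, RuntimeError):
    """A Gibbs sweep or linear solve failed on a specific LD block."""
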