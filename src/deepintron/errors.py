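"""Exception hierarchy shared across the package.

All data-level failures derive from :class:`DataError` so the CLI can map
them onto a single nonzero exit status distinct from usage errors.
"""


class DataError(Exception):
    """Base class for errors caused by invalid or inconsistent input data."""


class ReferenceMismatchError(DataError):
    """A variant's REF allele disagrees with the provided reference context."""


class InsufficientContextError(DataError):
    """Left-alignment needs sequence upstream of the provided context window."""


class ContractViolationError(DataError):
    """An operation was invoked on inputs that violate its preconditions."""


class VcfParseError(DataError):
    """A VCF record could not be parsed."""


class StructuralError(DataError):
    """A pedigree or table is structurally invalid (e.g. dangling parent id)."""


class AmbiguousScoreError(DataError):
    """A score table holds conflicting rows for one variant key."""


class UndefinedFrequencyError(DataError):
    """Allele frequency requested for a variant with zero called alleles."""


class ParameterError(DataError):
    """A run parameter is outside its valid range (e.g. k > number of callers)."""
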