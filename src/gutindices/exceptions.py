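"""Exception hierarchy.

Two branches matter for callers: :class:`InputError` (malformed or
inconsistent inputs; the CLI exits 1) and :class:`ComputationError`
(well-formed input for which the requested quantity is undefined or a
stage failed; the CLI exits 2).
"""


class GutIndicesError(Exception):
    """Base class for all package errors."""


class InputError(GutIndicesError):
    """Invalid, malformed, or inconsistent input data or configuration."""


class MalformedLineageError(InputError):
    """A taxonomic lineage string could not be parsed."""


class FormatError(InputError):
    """A file does not conform to its expected tabular layout."""


class ValidationError(InputError):
    """A value violates a stated constraint (e.g. negative abundance)."""


class ConflictError(InputError):
    """Contradictory duplicate entries in a classification table."""


class ConfigError(InputError):
    """Invalid simulator or pipeline configuration."""


class AmbiguityError(InputError):
    """A panel species matched more than one distinct lineage in a sample."""


class EmptyInputError(InputError):
    """An operation received an empty cohort or table."""


class InsufficientCohortError(InputError):
    """Too few samples for a cohort-referenced statistic."""


class ComputationError(GutIndicesError):
    """A quantity is undefined for otherwise valid input."""


class DegenerateSampleError(ComputationError):
    """A sample with zero total abundance cannot be normalized."""


class NoClassifiedMassError(ComputationError):
    """Neither aerotolerant nor strict-anaerobe mass is present."""


class UndefinedScoreError(ComputationError):
    """A score ratio has a zero term and no pseudocount was allowed."""
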