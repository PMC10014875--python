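"""Exception hierarchy for the explore package.

Every error raised deliberately by the package derives from
:class:`ExploreError`, so callers (and the CLI) can distinguish usage
errors from genuine bugs.
"""


class ExploreError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ExploreError):
    """An arena / project configuration violates its invariants."""


class BoundsError(ExploreError):
    """A region of interest or frame index lies outside the valid range."""


class ConsistencyError(ExploreError):
    """Two objects that must agree in length or schema do not."""


class SchemaError(ExploreError):
    """A class scheme mismatch or an unknown class name."""


class ConstraintError(ExploreError):
    """A sampling-plan constraint (e.g. j < i*n) is violated."""


class UndefinedDIError(ExploreError):
    """Discrimination index requested with zero total exploration time."""


class UndefinedCorrelationError(ExploreError):
    """Rank correlation requested on constant input."""


class FormatError(ExploreError):
    """A file is not in the expected on-disk format."""


class WorkflowError(ExploreError):
    """A pipeline stage was run before its prerequisites exist."""
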