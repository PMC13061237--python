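"""Typed exceptions raised across the package.

All errors derive from :class:`CohortFlowError` so callers can catch the
package's failures with a single except clause while tests can pin down
the specific failure mode.
"""


class CohortFlowError(Exception):
    """Base class for all cohortflow errors."""


class ConfigurationError(CohortFlowError):
    """An invalid option or variable declaration (e.g. unknown variable type)."""


class SchemaError(CohortFlowError):
    """A declared column is absent from the input table."""


class DataError(CohortFlowError):
    """Cell contents incompatible with the declared variable type."""


class DegenerateInputError(CohortFlowError):
    """A standardized difference is undefined (zero pooled variance with
    unequal locations, or a proportion contrast outside the covariance range)."""


class ValidationError(CohortFlowError):
    """A flow-consistency rule was violated (e.g. an exclusion step that
    removes nobody under strict validation)."""


class ConsistencyError(CohortFlowError):
    """Cohort states disagree (filtered rows not a subset, size increase)."""


class DetectionError(CohortFlowError):
    """Automatic variable-type detection cannot classify a column."""
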