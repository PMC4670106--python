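"""Exception hierarchy for the hdbrain pipeline.

Every stage raises a subclass of :class:`HdbrainError` so callers (the CLI
and the pipeline driver) can distinguish user errors from bugs.
"""


class HdbrainError(Exception):
    """Base class for all hdbrain errors."""


class ConfigurationError(HdbrainError):
    """Invalid parameter value (non-positive dimension, bad threshold, ...)."""


class SchemaError(HdbrainError):
    """Malformed input table: duplicate identifiers, missing columns, bad cells."""


class LabelingError(HdbrainError):
    """A sample carries an unknown or missing group label."""


class NormalizationError(HdbrainError):
    """Size-factor computation failed (e.g. empty reference gene set)."""


class DesignError(HdbrainError):
    """Regression design is degenerate (collinear columns, rank deficiency)."""


class AssociationError(HdbrainError):
    """Covariate association cannot be computed (constant covariate, n too small)."""


class InputError(HdbrainError):
    """Invalid value passed to a statistical routine."""
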