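"""Exception hierarchy shared across the package.

Every error raised by ctquant derives from :class:`CtQuantError`, so callers
(including the CLI, which maps them to exit code 2) can catch one type.
"""


class CtQuantError(Exception):
    """Base class for all ctquant errors."""


class FormatError(CtQuantError):
    """A file does not conform to the expected tabular format."""


class ValidationError(CtQuantError):
    """Parsed data violate a domain invariant."""


class InsufficientDataError(CtQuantError):
    """Too few observations to perform the requested computation."""


class MissingAssayError(CtQuantError):
    """A required assay has no detected measurement for a sample."""


class CurveQualityError(CtQuantError):
    """A standard curve fit is unusable (e.g. non-negative slope)."""


class QCError(CtQuantError):
    """A quality-control prerequisite is not met."""


class DegenerateDesignError(CtQuantError):
    """A regression design matrix is singular (constant covariate)."""
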