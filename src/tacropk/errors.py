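"""Exception hierarchy.

``ValidationError`` covers malformed user input (bad CSV rows, impossible
covariates, inconsistent subject sets); ``ConfigError`` covers impossible
simulation or run configurations.  The CLI maps the whole ``TacropkError``
family to exit code 1 and anything else to exit code 2.
"""


class TacropkError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TacropkError):
    """Input data violates a documented contract."""


class ConfigError(TacropkError):
    """A configuration object is internally inconsistent."""


class InsufficientDataError(ValidationError):
    """Too few usable observations for the requested computation."""


class DegenerateFitError(ValidationError):
    """A regression or profile is degenerate (constant predictor, zero AUC)."""
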