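"""Exception types shared across the pipeline."""


class ESLinesError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ESLinesError, ValueError):
    """A generator or model was configured with an out-of-range parameter."""


class InvalidInputError(ESLinesError, ValueError):
    """An input array or table violates a documented precondition."""


class IncompleteForcingError(ESLinesError, ValueError):
    """A forcing stack is missing a required month or variable."""


class InsufficientDataError(ESLinesError, ValueError):
    """Too few observations to carry out the requested computation."""


class FormMismatchError(ESLinesError, ValueError):
    """The requested functional form is inconsistent with the fitted data."""


class AlignmentError(ESLinesError, ValueError):
    """Yearly data sources do not cover the same set of years."""


class ConfigError(ESLinesError, ValueError):
    """A run configuration failed schema validation."""
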