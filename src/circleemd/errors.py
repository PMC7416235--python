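"""Exception types shared across the package."""


class CircleEmdError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CircleEmdError, ValueError):
    """Malformed or out-of-contract input."""


class InvalidKnotsError(InvalidInputError):
    """Spline knot positions are duplicated, unsorted, or out of range."""


class TooFewExtremaError(CircleEmdError, ValueError):
    """A signal does not carry enough extrema to build an envelope."""


class InvalidConfigError(CircleEmdError, ValueError):
    """A configuration value violates a stage precondition."""


class InvalidSelectionError(CircleEmdError, ValueError):
    """An index selection refers to components that do not exist."""
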