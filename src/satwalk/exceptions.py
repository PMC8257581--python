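"""Exception hierarchy used across the package."""


class SatwalkError(Exception):
    """Base class for all package errors."""


class ParameterError(SatwalkError, ValueError):
    """Invalid model or algorithm parameter."""


class ValidationError(SatwalkError, ValueError):
    """Malformed input data (tracks, tables, configs)."""


class InsufficientDataError(SatwalkError, ValueError):
    """Not enough data to carry out the requested computation."""


class FitError(SatwalkError, ValueError):
    """A curve fit could not be performed on the requested window."""
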