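"""Exception hierarchy shared across the package."""


class ScasimError(Exception):
    """Base class for all package errors."""


class FormatError(ScasimError, ValueError):
    """An input file could not be parsed or its parts are inconsistent."""


class ValidationError(ScasimError, ValueError):
    """A value violates a documented invariant."""


class ParameterError(ScasimError, ValueError):
    """A function argument is outside its admissible range."""


class EmptyResultError(ValidationError):
    """A filter or selection removed everything."""


class FitError(ScasimError, RuntimeError):
    """A statistical fit failed or is degenerate."""
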