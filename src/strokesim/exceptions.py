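"""Exception types shared across the package."""


class StrokesimError(Exception):
    """Base class for package errors."""


class InputError(StrokesimError, ValueError):
    """Invalid data supplied to an operation (coordinates, unknown nodes, ...)."""


class ConfigurationError(StrokesimError, ValueError):
    """Invalid parameter or run configuration."""


class ValidationError(StrokesimError, ValueError):
    """A file parsed, but its contents violate referential integrity."""
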