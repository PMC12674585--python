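"""Exception types shared across the package."""


class RootNIRSError(Exception):
    """Base class for package errors."""


class ConfigurationError(RootNIRSError):
    """Invalid simulation/pipeline configuration."""


class DegenerateInputError(RootNIRSError):
    """Input is degenerate for the requested operation (e.g. constant spectrum)."""


class SizingError(RootNIRSError):
    """Input too small for the requested operation."""
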