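"""Exception types shared across the package."""


class PelnetError(Exception):
    """Base class for all package errors."""


class FormatError(PelnetError):
    """A file could not be parsed as the requested format."""


class ValidationError(PelnetError):
    """Parsed or constructed data violates a documented invariant."""
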