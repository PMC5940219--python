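"""Exception hierarchy shared across modules."""


class RdriverError(Exception):
    """Base class for all package errors."""


class ValidationError(RdriverError):
    """Input violates a documented invariant (user-fixable)."""


class ParseError(RdriverError):
    """A file could not be parsed; message names the offending location."""
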