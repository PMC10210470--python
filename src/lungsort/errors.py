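class LungsortError(Exception):
    """Base class for all package errors."""


class ParseError(LungsortError):
    """A file could not be parsed; the message names the offending cell."""


class ValidationError(LungsortError):
    """Parsed data violate a structural invariant."""
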