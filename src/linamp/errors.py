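"""Exception types shared across the package."""


class LinampError(Exception):
    """Base class for package-specific errors."""


class ValidationError(LinampError, ValueError):
    """An input violated a documented precondition or invariant."""


class ParseError(LinampError, ValueError):
    """A file could not be parsed; the message names the offending line or field."""


class DesignInfeasibleError(LinampError, ValueError):
    """No primer placement can satisfy the hard geometric constraints."""
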