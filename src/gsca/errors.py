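"""Exception hierarchy shared across the package."""


class GscaError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GscaError):
    """A file could not be parsed (malformed line, missing column, ...)."""


class ValidationError(GscaError):
    """Inputs violate a documented precondition or invariant."""


class BuildError(GscaError):
    """A compendium or pipeline stage could not be constructed."""
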