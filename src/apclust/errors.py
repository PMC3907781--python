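"""Exception hierarchy shared across the package."""


class ApclustError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ApclustError):
    """An input file could not be parsed (message names the offending line)."""


class ValidationError(ApclustError):
    """An input value violates a documented precondition."""


class ConsistencyError(ApclustError):
    """Two artifacts that must describe the same data do not match."""


class DegenerateModelError(ApclustError):
    """The null model assigns zero expectation; a residual is undefined."""


class StateError(ApclustError):
    """An operation was called on an object missing required state."""
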