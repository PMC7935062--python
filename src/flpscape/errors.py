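"""Shared exception types."""


class InvalidArgumentError(ValueError):
    """An argument is outside its documented domain."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested computation."""


class MissingDataError(KeyError):
    """A required record (tip state, patch value, ...) is absent."""


class NonConvergenceError(RuntimeError):
    """Numerical optimization failed on every restart."""
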