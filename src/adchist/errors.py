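"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class StateError(RuntimeError):
    """Raised when an operation is attempted on an unfitted or inconsistent model."""
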