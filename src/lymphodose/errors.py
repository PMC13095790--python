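"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class FitError(RuntimeError):
    """Raised when an estimation routine cannot produce a usable result."""
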