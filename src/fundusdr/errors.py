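"""Exception types shared across the pipeline."""


class InvalidInputError(ValueError):
    """Raised when an operation receives data violating its preconditions."""


class InvalidConfigError(ValueError):
    """Raised when a configuration object violates its invariants."""


class PlacementError(RuntimeError):
    """Raised when synthetic lesions cannot be placed without overlap."""
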