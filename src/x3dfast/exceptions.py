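"""Shared exception types."""


class InvalidSpecError(ValueError):
    """A block or scene specification violates its invariants."""


class ConfigurationError(ValueError):
    """A run or model configuration is internally inconsistent."""


class MotionUndefinedError(ValueError):
    """Motion excitation requested on a single-frame clip; bypass the branch."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


class NotTrainedError(RuntimeError):
    """An operation requiring trained weights was called on an untrained model."""
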