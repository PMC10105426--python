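"""Exception taxonomy used across the package."""


class ThyrosegError(Exception):
    """Base class for package errors."""


class ConfigurationError(ThyrosegError, ValueError):
    """Invalid model/block/training configuration."""


class InputError(ThyrosegError, ValueError):
    """Invalid runtime input (shapes, label values, file contents)."""


class GenerationError(ThyrosegError, RuntimeError):
    """Phantom generation could not satisfy its geometric constraints."""
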