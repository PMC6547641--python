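"""Exception hierarchy shared across the package."""


class RnadistError(Exception):
    """Base class for all package-specific errors."""


class InputError(RnadistError, ValueError):
    """An argument violates an operation's preconditions."""


class ConfigError(RnadistError, ValueError):
    """A run configuration or decision file is inconsistent."""


class SegmentationFailure(RnadistError):
    """Automatic segmentation produced an empty or unusable mask.

    Carries the intermediate images of the failed pipeline stage so the
    caller can inspect what went wrong (gradient, binarized edges, ...).
    """

    def __init__(self, message: str, intermediates: dict | None = None):
        super().__init__(message)
        self.intermediates = intermediates or {}


class DegenerateFieldError(RnadistError):
    """An intensity field has zero total mass; moment metrics are undefined."""
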