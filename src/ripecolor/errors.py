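"""Exception types shared across the package."""


class RipecolorError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RipecolorError, ValueError):
    """An argument is outside its documented domain."""


class ConfigurationError(RipecolorError, ValueError):
    """A stage table, brightness standard or config file is malformed."""


class DegenerateInputError(RipecolorError, ValueError):
    """The input is formally valid but carries no usable signal
    (e.g. a constant image offered to Otsu thresholding)."""


class EmptyForegroundError(RipecolorError, ValueError):
    """Segmentation produced a mask with no foreground pixels."""


class PipelineError(RipecolorError, RuntimeError):
    """A multi-stage procedure failed; ``stage`` names the failed step."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
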