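"""Exception hierarchy shared across the pipeline stages."""


class RetlamError(Exception):
    """Base class for all package-specific errors."""


class BoundsError(RetlamError, ValueError):
    """A coordinate or ROI falls outside the image."""


class LandmarkDetectionError(RetlamError, ValueError):
    """The landmark search could not find the required neurite bands."""


class LandmarkValidationError(RetlamError, ValueError):
    """A landmark set violates the 0 < on < divider < off < 1 ordering."""


class NormalizationError(RetlamError, ValueError):
    """Normalization is undefined (all layer means are zero)."""


class ConfigError(RetlamError, ValueError):
    """Contradictory or incomplete run configuration."""


class PipelineError(RetlamError, RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""
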