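"""Exception hierarchy shared across the pipeline stages."""


class PulseWaveError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(PulseWaveError, ValueError):
    """An argument or configuration value is outside its documented range."""


class FormatError(PulseWaveError):
    """A recording or table file does not conform to the documented dialect."""


class SegmentationError(PulseWaveError):
    """No plausible cardiac cycles could be located in a recording."""


class QualityError(PulseWaveError):
    """Too few cycles survive the quality filter to support aggregation."""


class DetectionError(PulseWaveError):
    """A required fiducial landmark could not be located within a cycle."""


class WidthError(DetectionError):
    """The main wave never crosses the requested level on one flank."""


class ConfigError(ParameterError):
    """A pipeline configuration file contains an unknown or invalid key."""


class PipelineError(PulseWaveError):
    """A stage is missing the artifacts produced by an upstream stage."""
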