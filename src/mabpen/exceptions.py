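"""Exception hierarchy shared across the pipeline stages."""


class MabpenError(Exception):
    """Base class for all package errors."""


class ParameterError(MabpenError, ValueError):
    """A synthetic-generation or analysis parameter is invalid."""


class FormatError(MabpenError, IOError):
    """An input file does not match the expected layout (pages, shapes, schema)."""


class UsageError(MabpenError, ValueError):
    """An operation was called with arguments that violate its contract."""


class SegmentationError(MabpenError, RuntimeError):
    """Foreground extraction failed (e.g. constant channel, empty mask)."""


class ProfilingError(MabpenError, RuntimeError):
    """Intensity-vs-distance profiling cannot be computed."""


class FitError(MabpenError, RuntimeError):
    """Exponential decay fit failed or is unidentifiable."""


class ConfigError(MabpenError, ValueError):
    """A run configuration is missing or inconsistent."""


class EmptyVesselMaskWarning(UserWarning):
    """No vessel component survived filtering; vessel profiling is unavailable."""
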