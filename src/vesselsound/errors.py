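"""Exception hierarchy shared across the pipeline."""


class VesselSoundError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(VesselSoundError, ValueError):
    """A caller-supplied argument violates a precondition."""


class CoverageError(VesselSoundError):
    """Requested frequency/time range is not covered by the data."""


class DataQualityError(VesselSoundError):
    """Input data violate a quality contract (e.g. non-finite samples)."""


class ConfigError(VesselSoundError):
    """Configuration is internally inconsistent or incompatible with the data."""


class UndefinedMetricError(VesselSoundError):
    """A metric is undefined for the given inputs (e.g. no reference class)."""
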