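"""Package-wide error types."""


class CottonPhysError(Exception):
    """Base class for all package errors."""


class InvalidWeatherError(CottonPhysError, ValueError):
    """A weather record violates its invariants (e.g. tmax < tmin)."""


class WeatherGapError(CottonPhysError, ValueError):
    """The weather table is missing a day inside the requested range."""


class ConfigError(CottonPhysError, ValueError):
    """Invalid configuration: missing band, unknown key, bad value."""


class EmptyROIError(CottonPhysError, ValueError):
    """A region of interest contains no usable pixels."""


class InvalidReadingError(CottonPhysError, ValueError):
    """A light (PAR) reading violates its preconditions."""


class DegenerateInputError(CottonPhysError, ValueError):
    """An operation received input with no usable signal (zero denominator,
    zero variance, too few points)."""
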