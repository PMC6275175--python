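"""Exception hierarchy for the PLFA-SIP pipeline."""


class PlfaSipError(ValueError):
    """Base class for all domain errors raised by this package."""


class InvalidIsotopeValueError(PlfaSipError):
    """A delta or atom-fraction value outside its physical domain."""


class InvalidBiomarkerError(PlfaSipError):
    """A biomarker name or carbon count that cannot be interpreted."""


class InvalidMeasurementError(PlfaSipError):
    """A measured quantity outside its physical domain (e.g. negative mass)."""


class DegenerateEndmemberError(PlfaSipError):
    """Mixing endmembers coincide; the two-pool model is undefined."""


class InvalidChamberError(PlfaSipError):
    """Chamber geometry or sampling volumes are inconsistent."""


class InvalidIntervalError(PlfaSipError):
    """A time interval with non-positive duration."""


class MissingReferenceError(PlfaSipError):
    """No matched unamended control available for an excess computation."""


class DegenerateSeriesError(PlfaSipError):
    """A constant time series cannot be z-score normalized."""


class EmptyInputError(PlfaSipError):
    """An operation received an empty collection."""


class UndefinedRatioError(PlfaSipError):
    """A community ratio with a zero denominator."""


class SchemaError(PlfaSipError):
    """An input table violates the declared schema."""


class ConfigError(PlfaSipError):
    """A scenario or run configuration violates its invariants."""


class InsufficientUnitsError(PlfaSipError):
    """Too few replication units (fields) for a permutation contrast."""
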