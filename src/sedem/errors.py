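"""Exception hierarchy for the SeDeM toolkit.

Every error raised on bad scientific input derives from :class:`SedemError`
so callers can distinguish domain failures from programming errors.
"""


class SedemError(Exception):
    """Base class for all domain errors.

    Deliberately not a ``ValueError`` subclass: errors raised inside model
    validators must propagate as themselves rather than be collected into a
    pydantic ``ValidationError``.
    """


class InvalidMeasurementError(SedemError):
    """A raw measurement violates a physical invariant (e.g. zero volume)."""


class IncompleteTapSeriesError(SedemError):
    """The tapped-volume series is missing a required tap count."""


class TapRuleViolationError(SedemError):
    """|V500 - V1250| > 2 mL but no 2500-tap volume was recorded."""


class InconsistentDensitiesError(SedemError):
    """Bulk density exceeds tapped density."""


class DegenerateConeError(SedemError):
    """Cone base radii average to zero."""


class MeasurementOrderError(SedemError):
    """Moisture weights in an impossible order (dry > wet)."""


class NormalizationError(SedemError):
    """Sieve fractions do not sum to 100%."""


class NoDataError(SedemError):
    """An operation received an empty sample."""


class ConfigurationError(SedemError):
    """Unknown parameter id or invalid transform configuration."""


class MissingRadiusError(SedemError):
    """A radius profile is incomplete."""


class DegeneratePairError(SedemError):
    """Excipient and API compressibility radii are equal (Eq. denominator 0)."""


class InfeasibleTargetError(SedemError):
    """Target blend radius lies outside [RP, RE]."""


class CompositionError(SedemError):
    """No room left for API + lubricants in the composition."""


class ImpossibleGainError(SedemError):
    """Friability weights imply the tablets gained mass."""


class InsufficientSampleError(SedemError):
    """Too few units for the compendial test."""


class InfeasibleTruthError(SedemError):
    """Synthetic ground truth cannot be realized by any physical measurement set."""
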