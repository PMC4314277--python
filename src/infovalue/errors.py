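"""Exception hierarchy for infovalue.

Each distinct failure mode advertised by the public API has its own class so
callers (and the CLI) can react precisely.
"""


class InfoValueError(Exception):
    """Base class for all package errors."""


class ModelValidationError(InfoValueError):
    """A dynamics model violates its invariants (e.g. non-stochastic kernel row)."""


class NonStochasticRowError(ModelValidationError):
    """A transition-kernel row does not sum to one (names the state and action)."""


class ConfigurationError(InfoValueError):
    """Inputs are structurally inconsistent (missing labels, incomplete policy, ...)."""


class SchemaError(ConfigurationError):
    """A model-spec document does not match the published schema."""


class WeightSumError(SchemaError):
    """Model weights do not sum to one."""


class ImpossibleObservationError(InfoValueError):
    """An observed transition has zero likelihood under every positively weighted model."""


class InstanceTooLargeError(InfoValueError):
    """A brute-force or exact-enumeration routine refused an instance beyond its guard."""


class UndefinedGainError(InfoValueError):
    """A percentage gain was requested against a reference with zero mean value."""


class DomainError(InfoValueError):
    """A numeric argument is outside its physical domain (e.g. negative population)."""
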