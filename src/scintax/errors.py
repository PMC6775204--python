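"""Exception hierarchy for the selection-coordination-intention model."""


class ScintaxError(Exception):
    """Base class for all package errors."""


class ParameterError(ScintaxError, ValueError):
    """A model parameter is outside its admissible range."""


class IntegrationError(ScintaxError, ValueError):
    """Non-finite or misaligned quantities encountered during integration."""


class DegenerateFieldError(ScintaxError, ValueError):
    """Total field activation vanished; the centroid target is undefined.

    Unreachable when a neutral attractor with positive strength forces the
    field, so raising (rather than defaulting) flags a broken configuration.
    """


class WiringError(ScintaxError, ValueError):
    """A gesture was applied to a field for a different tract variable."""


class ContractError(ScintaxError, ValueError):
    """An operation was called outside its documented preconditions."""


class UndefinedBlendError(ScintaxError, ZeroDivisionError):
    """Blending weights sum to zero; the weighted-average target is undefined."""


class PropagationError(ScintaxError, ValueError):
    """A non-finite dynamic target reached the tract-variable dynamics."""


class UnachievedTargetError(ScintaxError, RuntimeError):
    """A gesture set's target was never achieved within the timeout."""


class ConfigError(ScintaxError, ValueError):
    """Scenario/word-form configuration is invalid; message names the path."""
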