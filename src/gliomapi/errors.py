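"""Exception types raised across the package."""


class GliomaPIError(Exception):
    """Base class for all package-specific errors."""


class InvalidFieldError(GliomaPIError):
    """A radial density field violates its invariants."""


class UnstableSettingsError(GliomaPIError):
    """Solver settings violate the stability contract of the chosen scheme."""


class CalibrationError(GliomaPIError):
    """Patient-specific parameters cannot be estimated from the observations."""


class ObservationError(GliomaPIError):
    """An observation table is malformed or violates modality constraints."""
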