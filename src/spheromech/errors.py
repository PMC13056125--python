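"""Exception types shared across the package."""


class SpheromechError(Exception):
    """Base class for package errors."""


class ValidationError(SpheromechError, ValueError):
    """An input object violates its documented invariants."""


class NoRuptureError(SpheromechError):
    """No force step exceeding the rupture threshold was found."""


class RampTooShortError(SpheromechError):
    """The loading ramp is shorter than the detrending window."""


class CalibrationError(SpheromechError):
    """A spectra/R0 calibration cannot be performed (e.g. zero overlap)."""


class ConvergenceError(SpheromechError):
    """An iterative simulation exceeded its step budget."""
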