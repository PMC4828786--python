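"""Exception hierarchy."""


class BalloonMechError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BalloonMechError, ValueError):
    """An argument violates a documented precondition."""


class ConvergenceError(BalloonMechError, RuntimeError):
    """The nonlinear solver failed to converge.

    Carries the last cavity volume (ml) at which equilibrium was reached,
    so a caller can restart or report a partial curve.
    """

    def __init__(self, message: str, last_volume_ml: float | None = None):
        super().__init__(message)
        self.last_volume_ml = last_volume_ml


class FitError(BalloonMechError, RuntimeError):
    """A material fit failed or produced an unstable parameter set."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ContourError(BalloonMechError, ValueError):
    """Contour extraction failed (no region, multiple regions, bad polyline)."""
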