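"""Exception hierarchy for model-validity and configuration failures."""


class CuticleUptakeError(Exception):
    """Base class for all package errors."""


class ParameterError(CuticleUptakeError, ValueError):
    """A configuration value is malformed or violates a physical invariant."""


class GeometryError(ParameterError):
    """Droplet spherical-cap geometry is undefined (contact angle out of (0, pi))."""


class DomainError(CuticleUptakeError, ValueError):
    """An input lies outside the mathematical domain of a constitutive law."""


class SteinerChainError(DomainError):
    """Fewer than three adsorbed molecules per pore circumference.

    The closed Steiner-chain construction relating monolayer coverage to
    pore radius is undefined below three tangent circles; reaching this
    regime means the monolayer model itself has broken down, not the solver.
    """


class PoreOverlapError(CuticleUptakeError):
    """Computed porosity reached 1: pore cross-sections overlap.

    Raised rather than clamped, because clamping would silently violate
    mass balance.
    """


class VolumeFractionError(DomainError):
    """Solute volume fraction exceeds 1 in the drop (vbar_AI * c_AI > 1)."""


class IntegrationError(CuticleUptakeError):
    """Time integration failed; carries the last accepted time and state."""

    def __init__(self, message, t_last=None, y_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last
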